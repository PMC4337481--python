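import numpy as np
import pandas as pd
import pytest

from tfregnet.io_formats import EdgeList, ExpressionMatrix


def make_matrix(values, gene_ids=None, groups=(2, 2), labels=("control", "tumor")):
    """Build an ExpressionMatrix from a 2-D array and per-group sample counts."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    assert sum(groups) == n_samples
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    sample_ids = [f"S{i}" for i in range(n_samples)]
    design = pd.Series([labels[0]] * groups[0] + [labels[1]] * groups[1],
                       index=sample_ids)
    return ExpressionMatrix(values=pd.DataFrame(values, index=gene_ids,
                                                columns=sample_ids),
                            design=design)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    return make_matrix(8 + 0.5 * rng.standard_normal((6, 12)), groups=(6, 6))


@pytest.fixture
def tiny_edges():
    return EdgeList(edges=(("G0", "G1"), ("G0", "G2"), ("G3", "G4")))
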