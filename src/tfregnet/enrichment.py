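"""Hypergeometric over-representation analysis of a gene list against
user-supplied gene-set collections (GMT).

For each set the one-sided upper-tail probability ``P(X >= overlap)`` is
computed from the hypergeometric distribution with population size equal to
the expression universe, ``set_size`` successes and ``list_size`` draws;
p-values are BH-adjusted across the tested sets. Sets with no overlap with
the universe are skipped (and logged). Depletion is not tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "hypergeom_ora"]


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    description: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p_value: float
    p_adjusted: float
    overlapping_genes: frozenset[str]


def hypergeom_ora(
    deg_ids: set[str],
    universe_ids: set[str],
    sets: GeneSetCollection,
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation of ``deg_ids``.

    ``deg_ids`` must be a subset of ``universe_ids``; each set is first
    intersected with the universe. Results are sorted by p ascending.
    """
    offenders = sorted(set(deg_ids) - set(universe_ids))
    if offenders:
        raise ValueError(f"gene list not contained in universe: {offenders[:10]}")
    universe = set(universe_ids)
    degs = set(deg_ids)
    n_universe = len(universe)
    n_list = len(degs)

    rows = []
    for set_id, (desc, members) in sets.sets.items():
        in_universe = members & universe
        if not in_universe:
            logger.info("set %r has no overlap with the universe; skipped", set_id)
            continue
        overlap = in_universe & degs
        k = len(overlap)
        # P(X >= k) with population n_universe, successes |set|, draws |list|
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(in_universe), n_list))
        p = min(max(p, 5e-324), 1.0)
        rows.append((set_id, desc, k, len(in_universe), overlap, p))

    if not rows:
        return []
    p_adj = multipletests([r[5] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            set_id=set_id,
            description=desc,
            overlap=k,
            set_size=set_size,
            list_size=n_list,
            universe_size=n_universe,
            p_value=p,
            p_adjusted=float(adj),
            overlapping_genes=frozenset(overlap),
        )
        for (set_id, desc, k, set_size, overlap, p), adj in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results
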