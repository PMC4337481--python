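"""Gene-level scoring of trimmed subnets and combined TF ranking.

Each trimmed subnet (the leading-edge TF-gene pairs of a hub) is re-scored
at the gene level: the background is the full expression universe ranked by
evidence of differential expression, ``r_j = -log10(p_j)`` descending, and
the objective set ``S_trimmed`` is the distinct genes of the trimmed subnet
(the TF itself included when it is on the matrix). The same running-sum
engine yields a gene-level ES, standardized against size-matched random
gene sets into ``Z_trimmed``. The final candidate score is

    Z_combined = Z_s + Z_trimmed

and TFs are ranked by it descending. An optional variant re-standardizes
the two Z components across all scored TFs before summing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .differential_expression import DEGRecord
from .subnet_scoring import SubnetScore, _null_es, running_es

logger = logging.getLogger(__name__)

__all__ = ["CombinedResult", "score_trimmed_genes", "rank_candidates",
           "annotate_regulated_degs", "combine_z_standardized"]


@dataclass(frozen=True)
class CombinedResult:
    tf_id: str
    trimmed_genes: frozenset[str]
    es_genes: float
    leading_genes: frozenset[str]
    z_trimmed: float
    z_s: float
    z_combined: float
    rank: int | None = None
    regulated_degs: frozenset[str] = frozenset()
    tf_is_deg: bool = False
    degenerate: bool = False


def score_trimmed_genes(
    deg_records: list[DEGRecord],
    subnet: SubnetScore,
    n_null: int = 1000,
    seed: int = 0,
    include_tf: bool = True,
    p_exponent: float = 1.0,
    convention: str = "positive",
) -> CombinedResult:
    """Score a subnet's trimmed genes against the ranked DEG profile.

    ``deg_records`` define the background universe; genes are ranked by
    ``-log10(p)`` descending (ties broken by gene id). ``S_trimmed`` is the
    set of target genes of the subnet's leading-edge pairs, plus the TF
    itself when expressed, intersected with the universe (absences logged).
    """
    universe = {r.gene_id for r in deg_records}
    trimmed = {tgt for _, tgt in subnet.leading_edge}
    if include_tf:
        trimmed.add(subnet.tf_id)
    absent = trimmed - universe
    if absent:
        logger.info("TF %r: %d trimmed genes absent from the universe",
                    subnet.tf_id, len(absent))
    trimmed &= universe
    if not trimmed:
        raise ValueError(f"TF {subnet.tf_id!r}: trimmed subnet empty after "
                         "intersecting with the expression universe")
    if len(trimmed) == len(universe):
        raise ValueError("trimmed subnet covers the whole universe")

    tiny = np.finfo(float).tiny
    ranked = sorted(deg_records, key=lambda r: (r.p_value, r.gene_id))
    weights = np.array([-math.log10(max(r.p_value, tiny)) for r in ranked])
    member = np.array([r.gene_id in trimmed for r in ranked])

    es, leading_idx = running_es(weights, member, p_exponent, convention)
    rng = np.random.default_rng(seed)
    null = _null_es(weights, len(ranked), int(member.sum()), n_null, rng,
                    p_exponent, convention)
    null_sd = float(null.std())
    degenerate = null_sd == 0.0 or subnet.degenerate
    if null_sd == 0.0:
        logger.warning("gene-level null ES sd is zero for TF %r", subnet.tf_id)
    z_trimmed = math.nan if null_sd == 0.0 else (es - float(null.mean())) / null_sd

    return CombinedResult(
        tf_id=subnet.tf_id,
        trimmed_genes=frozenset(trimmed),
        es_genes=es,
        leading_genes=frozenset(ranked[i].gene_id for i in leading_idx),
        z_trimmed=float(z_trimmed),
        z_s=subnet.z_s,
        z_combined=float(subnet.z_s + z_trimmed),
        degenerate=degenerate,
    )


def combine_z_standardized(results: list[CombinedResult]) -> list[CombinedResult]:
    """Variant of the combined score: re-standardize ``Z_s`` and
    ``Z_trimmed`` across the scored TFs (zero mean, unit sd) before
    summing. Requires >= 2 non-degenerate results."""
    ok = [r for r in results if not r.degenerate]
    if len(ok) < 2:
        raise ValueError("need >= 2 non-degenerate results to standardize")
    zs = np.array([r.z_s for r in ok])
    zt = np.array([r.z_trimmed for r in ok])

    def _std(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    zs_p, zt_p = _std(zs), _std(zt)
    out = []
    for r in results:
        if r.degenerate:
            out.append(r)
        else:
            i = ok.index(r)
            out.append(replace(r, z_combined=float(zs_p[i] + zt_p[i])))
    return out


def rank_candidates(results: list[CombinedResult], top_k: int = 5) -> list[CombinedResult]:
    """Rank TFs by ``Z_combined`` descending (ties by tf id; degenerate
    scores last) and return the top ``top_k`` with ranks assigned."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")

    def key(r: CombinedResult):
        z = -math.inf if (r.degenerate or math.isnan(r.z_combined)) else r.z_combined
        return (-z, r.tf_id)

    ordered = sorted(results, key=key)
    ranked = [replace(r, rank=i + 1) for i, r in enumerate(ordered)]
    return ranked[:top_k]


def annotate_regulated_degs(result: CombinedResult,
                            deg_records: list[DEGRecord]) -> CombinedResult:
    """Attach the DEGs among the trimmed-subnet genes, and flag whether the
    TF itself is differentially expressed."""
    deg_ids = {r.gene_id for r in deg_records if r.is_deg}
    regulated = frozenset(result.trimmed_genes & deg_ids) - {result.tf_id}
    return replace(result,
                   regulated_degs=frozenset(regulated),
                   tf_is_deg=result.tf_id in deg_ids)
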