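"""Hub-TF subnet scoring with a weighted running-sum enrichment score.

Hub TFs (out-degree strictly above a cut-off, default 15, among
filter-passing edges) define subnets: the objective set ``S`` is the TF's
passing edges, the background ``E`` is *all* passing edges ranked by delta
descending. Walking down the ranked background,

    P_hit(S, i)  = sum_{j in S, j <= i} |r_j|^P / N_R,   N_R = sum_{j in S} |r_j|^P
    P_miss(S, i) = sum_{j not in S, j <= i} 1 / (N - N_H)

with ``r_j`` the delta of edge ``j`` and ``P = 1`` by default. The
enrichment score is the maximum deviation ``max_i (P_hit - P_miss)``
(positive-deviation convention; a max-|deviation| variant is available).
Members at ranks up to the maximizing position form the *leading edge*;
edges beyond it do not contribute and are trimmed from the subnet.

Significance: the ES is standardized against ``n_null`` size-matched
random subsets of the background,

    Z_s = (ES - mean(ES_null)) / sd(ES_null).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .network_weighting import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = ["SubnetScore", "select_hub_tfs", "running_es", "score_subnet",
           "DEFAULT_MIN_DEGREE"]

DEFAULT_MIN_DEGREE = 15


@dataclass(frozen=True)
class SubnetScore:
    tf_id: str
    member_edges: tuple[tuple[str, str], ...]  # S, in background rank order
    es: float
    leading_edge: tuple[tuple[str, str], ...]  # trimmed subnet (contributing pairs)
    null_es: np.ndarray
    null_mean: float
    null_sd: float
    z_s: float
    degenerate: bool
    n_background: int
    n_members: int


def select_hub_tfs(network: WeightedNetwork, min_degree: int = DEFAULT_MIN_DEGREE,
                   passing_only: bool = True) -> list[str]:
    """TFs with out-degree strictly greater than ``min_degree``, sorted by
    degree descending then tf id. Degree counts filter-passing edges by
    default; set ``passing_only=False`` to count the unfiltered network."""
    degrees = network.degrees(passing_only=passing_only)
    hubs = [(tf, d) for tf, d in degrees.items() if d > min_degree]
    hubs.sort(key=lambda td: (-td[1], td[0]))
    if not hubs:
        logger.warning("no TF exceeds degree %d", min_degree)
    return [tf for tf, _ in hubs]


def running_es(
    ranked_weights: np.ndarray,
    membership: np.ndarray,
    p_exponent: float = 1.0,
    convention: str = "positive",
) -> tuple[float, list[int]]:
    """Enrichment score of a member set over a ranked, weighted background.

    ``ranked_weights`` must be sorted descending by the caller (validated);
    ``membership`` is a boolean vector of the same length. Returns the ES
    and the member indices at ranks up to the maximizing position (the
    leading edge). ``convention="positive"`` takes the maximum of
    ``P_hit - P_miss``; ``"max_abs"`` takes the signed deviation of largest
    magnitude (leading edge taken below the maximizing position when the
    deviation is negative).
    """
    w = np.asarray(ranked_weights, dtype=float)
    member = np.asarray(membership, dtype=bool)
    n = w.size
    if n < 2 or member.size != n:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.any(np.diff(w) > 1e-12):
        raise ValueError("ranked_weights must be sorted descending")
    n_h = int(member.sum())
    if n_h == 0:
        raise ValueError("empty member set")
    if n_h == n:
        raise ValueError("member set equals the background (P_miss undefined)")
    if convention not in ("positive", "max_abs"):
        raise ValueError(f"unknown convention {convention!r}")

    wp = np.abs(w) ** p_exponent
    hit_w = np.where(member, wp, 0.0)
    n_r = hit_w.sum()
    if n_r == 0.0:
        raise ValueError("all member weights are zero (N_R = 0)")
    p_hit = np.cumsum(hit_w) / n_r
    p_miss = np.cumsum(~member) / (n - n_h)
    dev = p_hit - p_miss

    if convention == "positive":
        pos = int(np.argmax(dev))
        es = float(dev[pos])
        leading = [i for i in range(pos + 1) if member[i]]
    else:
        pos = int(np.argmax(np.abs(dev)))
        es = float(dev[pos])
        if es >= 0:
            leading = [i for i in range(pos + 1) if member[i]]
        else:
            leading = [i for i in range(pos + 1, n) if member[i]]
    return es, leading


def _null_es(weights: np.ndarray, n: int, n_h: int, n_null: int,
             rng: np.random.Generator, p_exponent: float,
             convention: str) -> np.ndarray:
    """ES of ``n_null`` uniform size-``n_h`` subsets of the background."""
    out = np.empty(n_null)
    for i in range(n_null):
        member = np.zeros(n, dtype=bool)
        member[rng.choice(n, size=n_h, replace=False)] = True
        if not np.any(weights[member] > 0):
            out[i] = 0.0  # degenerate draw: no weighted mass to accumulate
            continue
        out[i] = running_es(weights, member, p_exponent, convention)[0]
    return out


def score_subnet(
    network: WeightedNetwork,
    tf_id: str,
    n_null: int = 1000,
    seed: int = 0,
    p_exponent: float = 1.0,
    convention: str = "positive",
) -> SubnetScore:
    """Score one TF's subnet against the full ranked edge background.

    Background = all filter-passing edges ranked by delta descending (ties
    broken by edge id for determinism); members = the TF's passing edges.
    The null is ``n_null`` size-matched uniform subsets of the background.
    A zero null sd flags the score degenerate (``z_s = nan``) instead of
    dividing by zero.
    """
    passing = sorted(network.passing_edges,
                     key=lambda e: (-e.delta, e.tf_id, e.target_id))
    if len(passing) < 2:
        raise ValueError("network has fewer than 2 passing edges")
    member = np.array([e.tf_id == tf_id for e in passing])
    if not member.any():
        raise ValueError(f"TF {tf_id!r} has no passing edges")
    if member.all():
        raise ValueError(f"TF {tf_id!r} owns the entire background")
    weights = np.array([e.delta for e in passing])

    es, leading_idx = running_es(weights, member, p_exponent, convention)
    rng = np.random.default_rng(seed)
    null = _null_es(weights, len(passing), int(member.sum()), n_null, rng,
                    p_exponent, convention)
    null_mean = float(null.mean())
    null_sd = float(null.std())
    degenerate = null_sd == 0.0
    if degenerate:
        logger.warning("null ES sd is zero for TF %r; z flagged degenerate", tf_id)
    z = math.nan if degenerate else (es - null_mean) / null_sd

    return SubnetScore(
        tf_id=tf_id,
        member_edges=tuple(e.edge_id for e, m in zip(passing, member) if m),
        es=es,
        leading_edge=tuple(passing[i].edge_id for i in leading_idx),
        null_es=null,
        null_mean=null_mean,
        null_sd=null_sd,
        z_s=float(z),
        degenerate=degenerate,
        n_background=len(passing),
        n_members=int(member.sum()),
    )
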