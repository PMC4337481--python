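"""Edge weighting by within-group rank correlation and permutation filtering.

For each TF -> target edge the Spearman coefficient is computed separately
within each sample group (``r1``, ``r2``). Two summaries follow:

* ``weight = |r1 + r2| / 2`` — the absolute mean, measuring consistent
  co-expression across conditions;
* ``delta  = |r1 - r2| / 2`` — the absolute half-difference (the "weighted
  coefficient"), measuring *differential* co-regulation between conditions.

Edges are then screened against a permutation null: sample-to-group labels
are reshuffled (group sizes preserved), deltas recomputed, and all null
deltas pooled into one empirical distribution. By default an edge passes
the filter when its observed delta exceeds the null's 90th percentile
(``keep_above``); ``drop_above`` inverts the rule for users who want the
literal complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .io_formats import EdgeList, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryEdge",
    "WeightedNetwork",
    "spearman_rho",
    "edge_weight",
    "edge_delta",
    "weight_edges",
    "permutation_filter",
]


def edge_weight(r_group1: float, r_group2: float) -> float:
    """Edge weight: absolute mean of the two within-group coefficients."""
    return abs(r_group1 + r_group2) / 2.0


def edge_delta(r_group1: float, r_group2: float) -> float:
    """Differential (weighted) coefficient: absolute half-difference."""
    return abs(r_group1 - r_group2) / 2.0


@dataclass(frozen=True)
class RegulatoryEdge:
    """One TF -> target pair with its two within-group Spearman
    coefficients, weight ``|r1+r2|/2`` and delta ``|r1-r2|/2``."""

    tf_id: str
    target_id: str
    r_group1: float
    r_group2: float
    weight: float
    delta: float
    passed_filter: bool = False

    @property
    def edge_id(self) -> tuple[str, str]:
        return (self.tf_id, self.target_id)


@dataclass(frozen=True)
class WeightedNetwork:
    """Weighted, permutation-filtered edge set with TF out-degrees."""

    edges: tuple[RegulatoryEdge, ...]
    permutation_threshold: float
    n_permutations: int
    quantile: float
    mode: str
    seed: int

    @property
    def passing_edges(self) -> tuple[RegulatoryEdge, ...]:
        return tuple(e for e in self.edges if e.passed_filter)

    def degrees(self, passing_only: bool = True) -> dict[str, int]:
        """TF out-degree; by default counts only filter-passing edges."""
        out: dict[str, int] = {}
        for e in self.edges:
            if passing_only and not e.passed_filter:
                continue
            out[e.tf_id] = out.get(e.tf_id, 0) + 1
        return out


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson product-moment correlation of the
    average ranks (ties share the mean rank).

    Returns 0.0 (logged) when either vector is constant, where the
    coefficient is otherwise undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need >= 3 observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    rx = rankdata(x)
    ry = rankdata(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0.0 or sy == 0.0:
        logger.warning("constant vector in spearman_rho; returning 0")
        return 0.0
    return float((dx * dy).sum() / (sx * sy))


def _rank_z(values: np.ndarray) -> np.ndarray:
    """Row-wise standardized average ranks; constant rows map to zeros,
    so downstream dot products give the rho=0 convention for free."""
    r = rankdata(values, axis=1)
    r -= r.mean(axis=1, keepdims=True)
    norm = np.sqrt((r * r).sum(axis=1, keepdims=True))
    np.divide(r, norm, out=r, where=norm > 0)
    return r


def _edge_rhos(values: np.ndarray, cols: np.ndarray,
               tf_idx: np.ndarray, tgt_idx: np.ndarray) -> np.ndarray:
    """Spearman rho for each (tf, target) row pair over the given columns."""
    z = _rank_z(values[:, cols])
    return np.einsum("ij,ij->i", z[tf_idx], z[tgt_idx])


def weight_edges(matrix: ExpressionMatrix, edges: EdgeList) -> list[RegulatoryEdge]:
    """Compute per-group Spearman coefficients, weight and delta for every
    edge whose TF and target are both on the matrix.

    Edges naming an absent gene are dropped (count logged); an empty result
    is an error.
    """
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    retained: list[tuple[str, str]] = []
    n_dropped = 0
    for tf, tgt in edges.edges:
        if tf in gene_pos and tgt in gene_pos:
            retained.append((tf, tgt))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("dropped %d edges with genes absent from the matrix", n_dropped)
    if not retained:
        raise ValueError("no edges left after intersecting with the expression matrix")

    g1, g2 = matrix.groups
    cols1 = matrix.group_columns(g1)
    cols2 = matrix.group_columns(g2)
    if cols1.size < 3 or cols2.size < 3:
        raise ValueError("each group needs >= 3 samples for rank correlation")
    values = matrix.values.to_numpy()
    tf_idx = np.array([gene_pos[tf] for tf, _ in retained])
    tgt_idx = np.array([gene_pos[tgt] for _, tgt in retained])
    r1 = _edge_rhos(values, cols1, tf_idx, tgt_idx)
    r2 = _edge_rhos(values, cols2, tf_idx, tgt_idx)

    return [
        RegulatoryEdge(
            tf_id=tf,
            target_id=tgt,
            r_group1=float(a),
            r_group2=float(b),
            weight=edge_weight(float(a), float(b)),
            delta=edge_delta(float(a), float(b)),
        )
        for (tf, tgt), a, b in zip(retained, r1, r2)
    ]


def permutation_filter(
    matrix: ExpressionMatrix,
    edges: list[RegulatoryEdge],
    n_permutations: int = 1000,
    quantile: float = 0.90,
    mode: str = "keep_above",
    seed: int = 0,
) -> WeightedNetwork:
    """Screen edges against a label-permutation null of the delta statistic.

    The sample -> group assignment is reshuffled ``n_permutations`` times
    (group sizes preserved); the deltas of every edge under every shuffle
    are pooled into one null distribution whose ``quantile`` quantile is
    the threshold. Under ``keep_above`` (default) an edge passes iff its
    observed delta exceeds the threshold; ``drop_above`` inverts this.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    if mode not in ("keep_above", "drop_above"):
        raise ValueError(f"unknown mode {mode!r}")
    if not edges:
        raise ValueError("no edges to filter")

    # restrict to the genes appearing on edges: null cost then scales with
    # the network, not the matrix
    used = sorted({g for e in edges for g in (e.tf_id, e.target_id)})
    gene_pos = {g: i for i, g in enumerate(used)}
    tf_idx = np.array([gene_pos[e.tf_id] for e in edges])
    tgt_idx = np.array([gene_pos[e.target_id] for e in edges])
    values = matrix.values.loc[used].to_numpy()
    g1, _ = matrix.groups
    n1 = matrix.group_columns(g1).size
    n_samples = values.shape[1]

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(edges)))
    for p in range(n_permutations):
        perm = rng.permutation(n_samples)
        r1 = _edge_rhos(values, perm[:n1], tf_idx, tgt_idx)
        r2 = _edge_rhos(values, perm[n1:], tf_idx, tgt_idx)
        null[p] = np.abs(r1 - r2) / 2.0

    threshold = float(np.quantile(null.ravel(), quantile))
    flagged = []
    for e in edges:
        above = e.delta > threshold
        passed = above if mode == "keep_above" else not above
        flagged.append(replace(e, passed_filter=passed))
    n_pass = sum(e.passed_filter for e in flagged)
    logger.info("permutation filter (%s, q=%.2f): threshold %.4f, %d/%d edges pass",
                mode, quantile, threshold, n_pass, len(flagged))
    return WeightedNetwork(
        edges=tuple(flagged),
        permutation_threshold=threshold,
        n_permutations=n_permutations,
        quantile=quantile,
        mode=mode,
        seed=seed,
    )
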