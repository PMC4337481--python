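"""Synthetic two-group expression data with planted, known ground truth.

The generator emulates the statistical structure of a two-condition
microarray study feeding a TF-regulatory-network analysis:

* two (possibly unequal) sample groups on a log2-Gaussian expression scale;
* a subset of genes with a planted mean shift between groups (true DEGs);
* a TF -> target edge list in which a subset of hub TFs is *differentially
  co-regulated*: their TF-target correlation is ``planted_rho_group1``
  within group 1 and ``planted_rho_group2`` within group 2, realized by a
  Gaussian-copula conditional construction
  ``target_z = rho * tf_z + sqrt(1 - rho^2) * eps``
  so the population correlation equals the planted value exactly;
* all remaining genes and edges carry no systematic signal.

Everything is reproducible from the single integer seed in the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import EdgeList, ExpressionMatrix, GeneSetCollection

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "simulate_gene_sets",
    "paper_shape_config",
]

BASELINE_MEAN = 8.0  # typical log2 RMA-scale intensity


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults describe the reference scenario.

    The reference scenario is a balanced 20+20 design of 1,000 assayed
    genes plus 10 TFs, 50 planted DEGs at a log2 fold change of 2.5 over
    noise sd 0.5, and one differentially co-regulated hub whose TF-target
    correlation flips from 0.8 in group 1 to -0.2 in group 2. Planted DEGs
    are drawn preferentially from the targets of planted hubs so that
    differential co-regulation and differential expression coincide, as
    they would for a driver TF.
    """

    n_group1: int = 20
    n_group2: int = 20
    n_genes: int = 1000
    n_tfs: int = 10
    targets_per_tf: tuple[int, int] = (25, 25)
    n_planted_degs: int = 50
    deg_log2fc: float = 2.5
    n_planted_diffcoreg_tfs: int = 1
    planted_rho_group1: float = 0.8
    planted_rho_group2: float = -0.2
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 3 or self.n_group2 < 3:
            raise ValueError("each group needs >= 3 samples")
        if self.n_genes < 1 or self.n_tfs < 1:
            raise ValueError("need at least one gene and one TF")
        lo, hi = self.targets_per_tf
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid targets_per_tf range {self.targets_per_tf}")
        if hi * self.n_tfs > self.n_genes:
            raise ValueError(
                f"infeasible: {self.n_tfs} TFs x up to {hi} targets exceeds "
                f"{self.n_genes} genes (targets are disjoint across TFs)"
            )
        if self.n_planted_degs > self.n_genes:
            raise ValueError("more planted DEGs than genes")
        if self.n_planted_diffcoreg_tfs > self.n_tfs:
            raise ValueError("more planted diff-coregulated TFs than TFs")
        for rho in (self.planted_rho_group1, self.planted_rho_group2):
            if abs(rho) > 1:
                raise ValueError(f"correlation {rho} outside [-1, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the answer key for every downstream stage."""

    universe: tuple[str, ...]  # all gene ids in the matrix (TFs included)
    true_deg_ids: frozenset[str]
    true_diffcoreg_tf_ids: frozenset[str]
    edge_rho: dict[tuple[str, str], tuple[float, float]]  # (rho_g1, rho_g2) per edge

    def to_json(self, path: str | Path) -> None:
        payload = {
            "universe": list(self.universe),
            "true_deg_ids": sorted(self.true_deg_ids),
            "true_diffcoreg_tf_ids": sorted(self.true_diffcoreg_tf_ids),
            "edge_rho": {f"{tf}\t{tgt}": list(r) for (tf, tgt), r in self.edge_rho.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def paper_shape_config(**overrides) -> SimulationConfig:
    """Reference scenario with the unbalanced 23 vs 77 group sizes of a
    typical tumor/non-tumor cohort, to exercise unbalanced-design paths."""
    params = dict(n_group1=23, n_group2=77)
    params.update(overrides)
    return SimulationConfig(**params)


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionMatrix, EdgeList, GroundTruth]:
    """Generate (matrix, edges, truth) from ``config``, fully seeded.

    Gene ids are ``G0001..``; TF ids ``TF01..`` and TFs are rows of the
    matrix like any other gene. Targets are disjoint across TFs. Group
    labels are ``"group1"``/``"group2"``; fold changes downstream are
    group2 minus group1.
    """
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_group1, config.n_group2
    n_samples = n1 + n2

    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    tf_ids = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    all_ids = tf_ids + gene_ids

    # assign disjoint target blocks per TF
    sizes = rng.integers(config.targets_per_tf[0], config.targets_per_tf[1] + 1,
                         size=config.n_tfs)
    pool = list(rng.permutation(gene_ids))
    targets: dict[str, list[str]] = {}
    cursor = 0
    for tf, k in zip(tf_ids, sizes):
        targets[tf] = pool[cursor:cursor + int(k)]
        cursor += int(k)
    edges = tuple((tf, tgt) for tf in tf_ids for tgt in targets[tf])

    planted_tfs = list(tf_ids[: config.n_planted_diffcoreg_tfs])

    # planted DEGs: preferentially the targets of planted hubs, then fill
    planted_pool = [g for tf in planted_tfs for g in targets[tf]]
    deg_ids: list[str] = planted_pool[: config.n_planted_degs]
    if len(deg_ids) < config.n_planted_degs:
        rest = [g for g in gene_ids if g not in set(deg_ids)]
        extra = list(rng.choice(rest, size=config.n_planted_degs - len(deg_ids),
                                replace=False))
        deg_ids += extra

    # latent standard-normal TF scores, reused by the copula construction
    tf_z = rng.standard_normal((config.n_tfs, n_samples))
    gene_z = rng.standard_normal((config.n_genes, n_samples))

    edge_rho: dict[tuple[str, str], tuple[float, float]] = {}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    rho_pair = (config.planted_rho_group1, config.planted_rho_group2)
    for tf in planted_tfs:
        ti = tf_ids.index(tf)
        for tgt in targets[tf]:
            gi = gene_index[tgt]
            eps = gene_z[gi]  # independent of tf_z by construction
            z = np.empty(n_samples)
            for rho, sl in zip(rho_pair, (slice(0, n1), slice(n1, n_samples))):
                z[sl] = rho * tf_z[ti, sl] + np.sqrt(1.0 - rho * rho) * eps[sl]
            gene_z[gi] = z
            edge_rho[(tf, tgt)] = rho_pair
    for tf in tf_ids:
        for tgt in targets[tf]:
            edge_rho.setdefault((tf, tgt), (0.0, 0.0))

    values = np.empty((len(all_ids), n_samples))
    values[: config.n_tfs] = BASELINE_MEAN + config.noise_sd * tf_z
    values[config.n_tfs:] = BASELINE_MEAN + config.noise_sd * gene_z
    deg_set = frozenset(deg_ids)
    for g in deg_ids:
        values[config.n_tfs + gene_index[g], n1:] += config.deg_log2fc

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    design = pd.Series(["group1"] * n1 + ["group2"] * n2, index=sample_ids, name="group")
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=all_ids, columns=sample_ids),
        design=design,
    )
    truth = GroundTruth(
        universe=tuple(all_ids),
        true_deg_ids=deg_set,
        true_diffcoreg_tf_ids=frozenset(planted_tfs),
        edge_rho=edge_rho,
    )
    return matrix, EdgeList(edges=edges), truth


def simulate_gene_sets(truth: GroundTruth, n_sets: int, seed: int,
                       set_size: int = 30, enriched_fraction: float = 0.7) -> GeneSetCollection:
    """Gene sets for over-representation testing: the first set is enriched
    in true DEGs (``enriched_fraction`` of members, at least 60%), the rest
    are uniform draws from the universe."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not 0.6 <= enriched_fraction <= 1.0:
        raise ValueError("enriched_fraction must be in [0.6, 1.0]")
    rng = np.random.default_rng(seed)
    universe = np.asarray(truth.universe)
    degs = np.asarray(sorted(truth.true_deg_ids))
    non_degs = np.asarray([g for g in truth.universe if g not in truth.true_deg_ids])

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    n_from_degs = min(len(degs), max(1, round(enriched_fraction * set_size)))
    n_fill = set_size - n_from_degs
    members = set(rng.choice(degs, size=n_from_degs, replace=False))
    if n_fill > 0:
        members |= set(rng.choice(non_degs, size=min(n_fill, len(non_degs)), replace=False))
    sets["SET01"] = ("planted DEG-enriched set", frozenset(members))
    for i in range(2, n_sets + 1):
        draw = rng.choice(universe, size=min(set_size, len(universe)), replace=False)
        sets[f"SET{i:02d}"] = ("random background set", frozenset(draw))
    return GeneSetCollection(sets=sets)
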