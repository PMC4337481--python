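"""End-to-end orchestration: simulate/read -> DEG -> ORA -> weight ->
filter -> subnet scores -> combined TF ranking, with one config, seeded
reproducibility and a run manifest.

Every stage writes its artifact through :mod:`tfregnet.io_formats`, so each
stage can also be re-run standalone on the intermediate files. Identical
config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .differential_expression import (DEFAULT_FC_CUT, DEFAULT_P_CUT,
                                      DEFAULT_PRIOR_DF, DEGRecord, call_degs,
                                      moderated_t_test)
from .enrichment import hypergeom_ora
from .gene_scoring import (CombinedResult, annotate_regulated_degs,
                           combine_z_standardized, rank_candidates,
                           score_trimmed_genes)
from .io_formats import (EdgeList, ExpressionMatrix, read_edge_list,
                         read_expression_matrix, read_gmt, write_edge_list,
                         write_expression_matrix, write_gmt, write_network_sif)
from .network_weighting import permutation_filter, weight_edges
from .subnet_scoring import (DEFAULT_MIN_DEGREE, SubnetScore, score_subnet,
                             select_hub_tfs)
from .synthetic import SimulationConfig, simulate_dataset, simulate_gene_sets

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_all", "load_config",
           "write_deg_table", "write_subnet_table", "write_candidate_table"]

_TBL_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """All knobs of a full run. Either the three input paths or a
    ``simulate`` block must be provided."""

    out_dir: str = "tfregnet_out"
    matrix_path: str | None = None
    design_path: str | None = None
    edges_path: str | None = None
    gmt_path: str | None = None
    simulate: SimulationConfig | None = None
    # DEG stage
    p_cut: float = DEFAULT_P_CUT
    fc_cut: float = DEFAULT_FC_CUT
    prior_df: float = DEFAULT_PRIOR_DF
    use_adjusted_p: bool = False
    # permutation filter
    n_permutations: int = 1000
    quantile: float = 0.90
    filter_mode: str = "keep_above"
    # subnet / gene scoring
    min_degree: int = DEFAULT_MIN_DEGREE
    n_null: int = 1000
    top_k: int = 5
    standardize_z: bool = False
    include_tf_in_trimmed: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None and not (self.matrix_path and self.design_path
                                          and self.edges_path):
            raise ValueError("provide matrix/design/edges paths or a simulate block")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError(f"quantile must be in (0, 1), got {self.quantile}")
        for name in ("p_cut", "fc_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.filter_mode not in ("keep_above", "drop_above"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        for name in ("matrix_path", "design_path", "edges_path", "gmt_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")


@dataclass
class RunManifest:
    config: dict
    version: str
    counts: dict
    artifacts: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True),
            encoding="utf-8")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    sim = raw.pop("simulate", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if sim is not None:
        cfg.simulate = SimulationConfig(**sim)
    return cfg


def write_deg_table(records: list[DEGRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tlog2fc\tt\tp\tp_adj\tis_deg\tdirection\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{_TBL_FMT % r.log2fc}\t{_TBL_FMT % r.t_stat}\t"
                     f"{r.p_value:.6e}\t{r.p_adjusted:.6e}\t"
                     f"{int(r.is_deg)}\t{r.direction}\n")


def write_subnet_table(scores: list[SubnetScore], degrees: dict[str, int],
                       path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf_id\tdegree\tn_members\tes\tn_leading\tnull_mean\tnull_sd\tz_s\n")
        for s in scores:
            fh.write(f"{s.tf_id}\t{degrees.get(s.tf_id, 0)}\t{s.n_members}\t"
                     f"{_TBL_FMT % s.es}\t{len(s.leading_edge)}\t"
                     f"{_TBL_FMT % s.null_mean}\t{_TBL_FMT % s.null_sd}\t"
                     f"{_TBL_FMT % s.z_s}\n")


def write_candidate_table(results: list[CombinedResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\ttf_id\tregulated_degs\tz_s\tz_trimmed\tz_combined\ttf_is_deg\n")
        for r in results:
            fh.write(f"{r.rank}\t{r.tf_id}\t{','.join(sorted(r.regulated_degs))}\t"
                     f"{_TBL_FMT % r.z_s}\t{_TBL_FMT % r.z_trimmed}\t"
                     f"{_TBL_FMT % r.z_combined}\t{int(r.tf_is_deg)}\n")


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int | float] = {}
    artifacts: dict[str, str] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        if config.simulate is not None:
            _stage("simulate")
            matrix, edges, truth = simulate_dataset(config.simulate)
            write_expression_matrix(matrix, out / "matrix.tsv", out / "design.tsv")
            write_edge_list(edges, out / "edges.tsv")
            truth.to_json(out / "truth.json")
            gmt = simulate_gene_sets(truth, n_sets=5, seed=config.simulate.seed)
            write_gmt(gmt, out / "gene_sets.gmt")
            artifacts.update(matrix=str(out / "matrix.tsv"),
                             design=str(out / "design.tsv"),
                             edges=str(out / "edges.tsv"),
                             truth=str(out / "truth.json"),
                             gene_sets=str(out / "gene_sets.gmt"))
        else:
            _stage("read inputs")
            matrix = read_expression_matrix(config.matrix_path, config.design_path)
            edges = read_edge_list(config.edges_path)
            gmt = read_gmt(config.gmt_path) if config.gmt_path else None
        counts["genes"] = matrix.n_genes
        counts["samples"] = matrix.n_samples
        counts["input_edges"] = len(edges)

        _stage("differential expression")
        records = moderated_t_test(matrix, prior_df=config.prior_df,
                                   p_cut=config.p_cut, fc_cut=config.fc_cut,
                                   use_adjusted_p=config.use_adjusted_p)
        up, down = call_degs(records)
        write_deg_table(records, out / "deg.tsv")
        artifacts["deg"] = str(out / "deg.tsv")
        counts["degs"] = len(up) + len(down)
        counts["degs_up"] = len(up)
        counts["degs_down"] = len(down)

        if gmt is not None:
            _stage("over-representation")
            deg_ids = {r.gene_id for r in records if r.is_deg}
            if deg_ids:
                enr = hypergeom_ora(deg_ids, set(matrix.gene_ids), gmt)
                with open(out / "enrichment.tsv", "w", encoding="utf-8") as fh:
                    fh.write("set_id\toverlap\tset_size\tlist_size\tuniverse\tp\tp_adj\n")
                    for e in enr:
                        fh.write(f"{e.set_id}\t{e.overlap}\t{e.set_size}\t"
                                 f"{e.list_size}\t{e.universe_size}\t"
                                 f"{e.p_value:.6e}\t{e.p_adjusted:.6e}\n")
                artifacts["enrichment"] = str(out / "enrichment.tsv")
                counts["enriched_sets_p05"] = sum(e.p_value < 0.05 for e in enr)

        _stage("network weighting")
        weighted = weight_edges(matrix, edges)
        counts["weighted_edges"] = len(weighted)

        _stage("permutation filter")
        network = permutation_filter(matrix, weighted,
                                     n_permutations=config.n_permutations,
                                     quantile=config.quantile,
                                     mode=config.filter_mode,
                                     seed=config.seed)
        attrs = write_network_sif(network.passing_edges, out / "network.sif")
        artifacts["network"] = str(out / "network.sif")
        artifacts["network_attributes"] = str(attrs)
        sidecar = {
            "threshold": network.permutation_threshold,
            "n_permutations": network.n_permutations,
            "quantile": network.quantile,
            "mode": network.mode,
            "seed": network.seed,
            "edges_kept": len(network.passing_edges),
            "edges_excluded": len(network.edges) - len(network.passing_edges),
        }
        (out / "filter.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True),
                                         encoding="utf-8")
        artifacts["filter"] = str(out / "filter.json")
        counts["edges_kept"] = sidecar["edges_kept"]
        counts["edges_excluded"] = sidecar["edges_excluded"]

        _stage("subnet scoring")
        hubs = select_hub_tfs(network, min_degree=config.min_degree)
        counts["hub_tfs"] = len(hubs)
        scores = [score_subnet(network, tf, n_null=config.n_null,
                               seed=config.seed + 1 + i)
                  for i, tf in enumerate(hubs)]
        write_subnet_table(scores, network.degrees(), out / "subnets.tsv")
        artifacts["subnets"] = str(out / "subnets.tsv")

        _stage("gene scoring")
        results = []
        for i, s in enumerate(scores):
            r = score_trimmed_genes(records, s, n_null=config.n_null,
                                    seed=config.seed + 1001 + i,
                                    include_tf=config.include_tf_in_trimmed)
            results.append(annotate_regulated_degs(r, records))
        if config.standardize_z and len(results) >= 2:
            results = combine_z_standardized(results)
        top = rank_candidates(results, top_k=config.top_k) if results else []
        write_candidate_table(top, out / "candidates.tsv")
        artifacts["candidates"] = str(out / "candidates.tsv")
        counts["candidates"] = len(top)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed (partial outputs in {out}): {exc}") from exc

    cfg_dict = dataclasses.asdict(config)
    manifest = RunManifest(config=cfg_dict, version=__version__,
                           counts=counts, artifacts=artifacts)
    manifest.to_json(out / "manifest.json")
    return manifest
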