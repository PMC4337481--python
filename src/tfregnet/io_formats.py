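"""Readers and writers for every external representation the pipeline touches.

All formats are plain text, UTF-8, tab-separated (no CSV dialect sniffing):

* expression matrix — TSV, header row of sample ids, first column gene ids,
  values assumed already log2-normalized;
* design — headerless two-column TSV ``sample_id<TAB>group`` with exactly
  two distinct group labels;
* edge list — headerless two-column TSV ``tf<TAB>target``, ``#`` comments;
* gene sets — standard GMT (``set_id<TAB>description<TAB>member...``);
* network export — SIF triples plus a sibling TSV of edge attributes.

Readers validate aggressively and fail with coordinates; nothing is skipped
silently (drops are logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "EdgeList",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "write_network_sif",
    "read_edge_attributes",
]

# float format that round-trips IEEE doubles through text exactly
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples log2-scale expression with a two-group design.

    ``values`` is a DataFrame indexed by gene id with sample-id columns;
    ``design`` maps every sample id to one of exactly two group labels.
    ``groups`` are the two labels in sorted order; all group-wise operations
    in the package treat ``groups[0]`` as the reference (fold changes are
    ``groups[1]`` minus ``groups[0]``).
    """

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")
        design = self.design.loc[list(self.values.columns)]
        labels = sorted(design.unique())
        if len(labels) != 2:
            raise ValueError(f"design must define exactly two groups, got {labels}")
        counts = design.value_counts()
        small = counts[counts < 2]
        if not small.empty:
            raise ValueError(f"each group needs >= 2 samples, got {counts.to_dict()}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        object.__setattr__(self, "design", design)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> tuple[str, str]:
        labels = sorted(self.design.unique())
        return labels[0], labels[1]

    def group_samples(self, label: str) -> list[str]:
        return list(self.design.index[self.design == label])

    def group_columns(self, label: str) -> np.ndarray:
        """Integer column positions of the samples in ``label``."""
        mask = (self.design.loc[list(self.values.columns)] == label).to_numpy()
        return np.flatnonzero(mask)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EdgeList:
    """Directed TF -> target pairs, deduplicated, no self-loops."""

    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for tf, tgt in self.edges:
            if tf == tgt:
                raise ValueError(f"self-loop edge {tf!r} -> {tgt!r}")
            if (tf, tgt) in seen:
                raise ValueError(f"duplicate edge {tf!r} -> {tgt!r}")
            seen.add((tf, tgt))

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def tf_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for tf, _ in self.edges:
            seen.setdefault(tf)
        return list(seen)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: set_id -> (description, members)."""

    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


def read_expression_matrix(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix and its sample->group design.

    Duplicate gene rows are collapsed to the single row with the highest
    variance across samples (a standard probe-to-gene collapse heuristic);
    each collapse is logged.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {raw[col].iloc[i]!r} at "
                f"gene {raw.index[i]!r} (row {i + 2}), sample {col!r} (column {j + 2})"
            )
        if converted.isna().any():
            i = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value at gene {raw.index[i]!r}, sample {col!r}")
        values[col] = converted

    if values.index.has_duplicates:
        variances = values.var(axis=1, ddof=1).to_numpy()
        keep = np.ones(len(values), dtype=bool)
        order = {}
        for i, gid in enumerate(values.index):
            order.setdefault(gid, []).append(i)
        n_collapsed = 0
        for gid, rows in order.items():
            if len(rows) > 1:
                best = rows[int(np.argmax(variances[rows]))]
                for r in rows:
                    keep[r] = r == best
                n_collapsed += 1
                logger.info("collapsed %d duplicate rows for gene %r (kept max-variance row)",
                            len(rows), gid)
        values = values.iloc[keep]
        logger.info("collapsed %d duplicated gene ids", n_collapsed)

    values.index.name = None
    values.columns.name = None
    design = read_design(design_path)
    missing = [s for s in values.columns if s not in design.index]
    if missing:
        raise ValueError(f"{design_path}: sample(s) missing from design: {missing}")
    return ExpressionMatrix(values=values, design=design.loc[list(values.columns)])


def read_design(path: str | Path) -> pd.Series:
    """Read a headerless two-column TSV mapping sample id to group label."""
    path = Path(path)
    samples: list[str] = []
    labels: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}")
            samples.append(parts[0])
            labels.append(parts[1])
    if not samples:
        raise ValueError(f"{path}: empty design file")
    return pd.Series(labels, index=samples, name="group")


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            design_path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="gene_id")
    with open(design_path, "w", encoding="utf-8") as fh:
        for sample, group in matrix.design.items():
            fh.write(f"{sample}\t{group}\n")


def read_edge_list(path: str | Path) -> EdgeList:
    """Read a two-column TSV of TF -> target pairs.

    Duplicates and self-loops are dropped (first occurrence kept, drops
    logged); ``#`` lines are comments. Whitespace other than the tab
    delimiter is not significant.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
            tf, tgt = parts
            if tf == tgt:
                n_self += 1
                logger.warning("%s:%d: dropping self-loop %r", path, lineno, tf)
                continue
            if (tf, tgt) in seen:
                n_dup += 1
                continue
            seen.add((tf, tgt))
            edges.append((tf, tgt))
    if not edges:
        raise ValueError(f"{path}: no edges")
    if n_dup or n_self:
        logger.info("%s: dropped %d duplicate and %d self-loop edges", path, n_dup, n_self)
    return EdgeList(edges=tuple(edges))


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tf, tgt in edges.edges:
            fh.write(f"{tf}\t{tgt}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: set_id TAB description TAB member..."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(parts)}")
            set_id, desc = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            sets[set_id] = (desc, members)
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def _attrs_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".attrs.tsv")


def write_network_sif(edges: Sequence, path: str | Path) -> Path:
    """Write weighted edges as SIF plus a sibling edge-attribute TSV.

    ``edges`` are objects carrying ``tf_id``, ``target_id``, ``r_group1``,
    ``r_group2``, ``weight`` and ``delta``. Returns the attribute-file path.
    Values are written with 17 significant digits so a re-read reproduces
    them exactly.
    """
    path = Path(path)
    attrs = _attrs_path(path)
    if len(edges) == 0:
        logger.warning("writing empty network to %s", path)
    with open(path, "w", encoding="utf-8") as fh:
        for e in edges:
            fh.write(f"{e.tf_id}\tregulates\t{e.target_id}\n")
    with open(attrs, "w", encoding="utf-8") as fh:
        fh.write("tf\ttarget\tr_group1\tr_group2\tweight\tdelta\n")
        for e in edges:
            vals = "\t".join(_FLOAT_FMT % v for v in
                             (e.r_group1, e.r_group2, e.weight, e.delta))
            fh.write(f"{e.tf_id}\t{e.target_id}\t{vals}\n")
    return attrs


def read_edge_attributes(path: str | Path) -> pd.DataFrame:
    """Read the edge-attribute TSV written next to a SIF export."""
    return pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
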