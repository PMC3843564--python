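"""Domain types and I/O for TF-gene connectivity patterns and expression data.

A gene regulatory network prior is a signed ternary matrix over genes (rows)
and transcription factors (columns): +1 for a documented activation, -1 for a
documented repression, 0 for no documented interaction.  Documented edges
whose regulatory direction is unknown are encoded +1, following the usual
curation convention, and are tracked through a ``direction_known`` mask so
that downstream sign fixing never anchors on them.

Expression data are strictly positive ratios relative to a control condition
(one matrix per biological replicate) and are analysed on the log10 scale.
The log base is fixed at 10 throughout the package.

Supported serializations:

* matrix-TSV: genes in rows, TFs in columns, header row of TF ids, first
  column of gene ids, cells in {-1, 0, 1}; an optional companion TSV of
  identical shape holds the {0, 1} ``direction_known`` mask.
* SIF-style edge list: three tab-separated columns
  ``tf <TAB> relation <TAB> gene`` with relation one of ``activates``,
  ``represses``, ``regulates`` ("regulates" marks a documented edge of
  unknown direction, stored as +1 with ``direction_known`` false).
* Expression TSV: header row of condition ids, first column of gene ids,
  decimal floats (positive ratios).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DomainError,
    EmptyRegulonError,
    EncodingError,
    LabelError,
)

LOG_BASE = 10

_RELATION_TO_ENTRY = {"activates": 1, "represses": -1, "regulates": 1}
_ENTRY_TO_RELATION = {(1, True): "activates", (-1, True): "represses", (1, False): "regulates"}


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise LabelError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True, eq=False)
class ConnectivityPattern:
    """Signed ternary m x p TF->gene connectivity structure.

    Parameters
    ----------
    gene_ids, tf_ids
        Ordered unique labels for the m genes (rows) and p TFs (columns).
    entries
        m x p integer matrix over {-1, 0, +1}.
    direction_known
        m x p boolean mask; False marks a documented edge whose regulatory
        direction was unknown (always stored as +1).  Defaults to all True
        on the support.
    """

    gene_ids: tuple
    tf_ids: tuple
    entries: np.ndarray
    direction_known: np.ndarray = None

    def __post_init__(self):
        gene_ids = tuple(str(g) for g in self.gene_ids)
        tf_ids = tuple(str(t) for t in self.tf_ids)
        _check_unique(gene_ids, "gene")
        _check_unique(tf_ids, "TF")
        entries = np.asarray(self.entries)
        if entries.shape != (len(gene_ids), len(tf_ids)):
            raise EncodingError(
                f"entries shape {entries.shape} does not match "
                f"{len(gene_ids)} genes x {len(tf_ids)} TFs"
            )
        if not np.isin(entries, (-1, 0, 1)).all():
            bad = entries[~np.isin(entries, (-1, 0, 1))][0]
            raise EncodingError(f"connectivity entries must be in {{-1, 0, 1}}; found {bad!r}")
        entries = entries.astype(np.int8)
        if self.direction_known is None:
            known = np.ones_like(entries, dtype=bool)
        else:
            known = np.asarray(self.direction_known, dtype=bool)
            if known.shape != entries.shape:
                raise EncodingError("direction_known mask shape must match entries")
        if (entries[~known] == -1).any():
            raise EncodingError(
                "an edge with unknown direction must be encoded +1, not -1"
            )
        empty = np.flatnonzero((entries != 0).sum(axis=0) == 0)
        if empty.size:
            raise EmptyRegulonError(
                f"TF {tf_ids[empty[0]]!r} regulates no gene (empty regulon)"
            )
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "tf_ids", tf_ids)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "direction_known", known)
        entries.setflags(write=False)
        known.setflags(write=False)

    # -- basic geometry -------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.gene_ids)

    @property
    def p(self) -> int:
        return len(self.tf_ids)

    @property
    def support(self) -> np.ndarray:
        """Boolean m x p mask of documented edges."""
        return self.entries != 0

    def in_degrees(self) -> np.ndarray:
        """Number of regulators per gene."""
        return (self.entries != 0).sum(axis=1)

    def regulon_sizes(self) -> np.ndarray:
        """Number of target genes per TF."""
        return (self.entries != 0).sum(axis=0)

    # -- derived views --------------------------------------------------
    def restrict(self, genes: Iterable[str] = None, tfs: Iterable[str] = None
                 ) -> "ConnectivityPattern":
        """Return the sub-pattern over the given labels (orders preserved).

        Raises :class:`EmptyRegulonError` if the restriction empties a
        retained TF's regulon.
        """
        genes = list(self.gene_ids) if genes is None else [g for g in self.gene_ids if g in set(genes)]
        tfs = list(self.tf_ids) if tfs is None else [t for t in self.tf_ids if t in set(tfs)]
        gi = [self.gene_ids.index(g) for g in genes]
        ti = [self.tf_ids.index(t) for t in tfs]
        return ConnectivityPattern(
            tuple(genes), tuple(tfs),
            self.entries[np.ix_(gi, ti)], self.direction_known[np.ix_(gi, ti)],
        )

    def reindex(self, gene_ids: Sequence[str], tf_ids: Sequence[str]) -> "ConnectivityPattern":
        """Return the same network with rows/columns permuted to the given orders."""
        if set(gene_ids) != set(self.gene_ids) or set(tf_ids) != set(self.tf_ids):
            raise AlignmentError("reindex labels must be a permutation of the pattern's labels")
        gi = [self.gene_ids.index(g) for g in gene_ids]
        ti = [self.tf_ids.index(t) for t in tf_ids]
        return ConnectivityPattern(
            tuple(gene_ids), tuple(tf_ids),
            self.entries[np.ix_(gi, ti)], self.direction_known[np.ix_(gi, ti)],
        )

    def same_network(self, other: "ConnectivityPattern") -> bool:
        """True if both patterns describe the same signed edge set with the
        same direction flags, regardless of row/column order."""
        if set(self.gene_ids) != set(other.gene_ids) or set(self.tf_ids) != set(other.tf_ids):
            return False
        o = other.reindex(self.gene_ids, self.tf_ids)
        return (np.array_equal(self.entries, o.entries)
                and np.array_equal(self.direction_known | (self.entries == 0),
                                   o.direction_known | (o.entries == 0)))


@dataclass(frozen=True, eq=False)
class ExpressionSet:
    """Replicate-wise positive expression-ratio matrices (genes x conditions).

    Ratios are dimensionless, relative to a control condition; NaN marks a
    missing measurement (dropped during :func:`align`, never imputed).
    """

    gene_ids: tuple
    condition_ids: tuple
    replicates: tuple  # of m x n float arrays
    log_base: int = field(default=LOG_BASE)

    def __post_init__(self):
        gene_ids = tuple(str(g) for g in self.gene_ids)
        condition_ids = tuple(str(c) for c in self.condition_ids)
        _check_unique(gene_ids, "gene")
        _check_unique(condition_ids, "condition")
        if len(condition_ids) < 2:
            raise DomainError("an expression set needs at least 2 conditions")
        if self.log_base != LOG_BASE:
            raise DomainError("log base is fixed at 10")
        reps = []
        shape = (len(gene_ids), len(condition_ids))
        if not self.replicates:
            raise DomainError("at least one replicate matrix is required")
        for r, mat in enumerate(self.replicates):
            mat = np.asarray(mat, dtype=float)
            if mat.shape != shape:
                raise AlignmentError(
                    f"replicate {r} has shape {mat.shape}, expected {shape}"
                )
            bad = np.argwhere(~np.isnan(mat) & (mat <= 0))
            if bad.size:
                i, j = bad[0]
                raise DomainError(
                    f"nonpositive expression ratio {mat[i, j]!r} for gene "
                    f"{gene_ids[i]!r}, condition {condition_ids[j]!r} (replicate {r})"
                )
            mat.setflags(write=False)
            reps.append(mat)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "condition_ids", condition_ids)
        object.__setattr__(self, "replicates", tuple(reps))

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    @property
    def n(self) -> int:
        return len(self.condition_ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def log_ratios(self) -> list:
        """Per-replicate log10 views of the ratio matrices."""
        return [np.log10(r) for r in self.replicates]

    def mean_log(self) -> np.ndarray:
        """Gene x condition mean of log10 ratios over replicates."""
        return np.mean(self.log_ratios(), axis=0)

    def has_missing(self) -> np.ndarray:
        """Per-gene boolean: any NaN in any replicate."""
        return np.any([np.isnan(r).any(axis=1) for r in self.replicates], axis=0)


@dataclass(frozen=True, eq=False)
class TFExpressionTable:
    """Expression ratios of the genes encoding the TFs (for parity checks).

    ``tf_ids`` are the labels of the TF-encoding genes; composite regulators
    (e.g. an obligate dimer written "A/B") are matched constituent by
    constituent against this table.
    """

    tf_ids: tuple
    condition_ids: tuple
    replicates: tuple  # of t x n float arrays

    def __post_init__(self):
        tf_ids = tuple(str(t) for t in self.tf_ids)
        condition_ids = tuple(str(c) for c in self.condition_ids)
        _check_unique(tf_ids, "TF gene")
        reps = []
        shape = (len(tf_ids), len(condition_ids))
        for r, mat in enumerate(self.replicates):
            mat = np.asarray(mat, dtype=float)
            if mat.shape != shape:
                raise AlignmentError(f"TF-expression replicate {r} has shape {mat.shape}, expected {shape}")
            if (mat[~np.isnan(mat)] <= 0).any():
                raise DomainError("TF expression ratios must be strictly positive")
            mat.setflags(write=False)
            reps.append(mat)
        object.__setattr__(self, "tf_ids", tf_ids)
        object.__setattr__(self, "condition_ids", condition_ids)
        object.__setattr__(self, "replicates", tuple(reps))

    def mean_log(self) -> np.ndarray:
        """TF-gene x condition mean of log10 ratios over replicates."""
        return np.mean([np.log10(r) for r in self.replicates], axis=0)


@dataclass(frozen=True)
class AlignReport:
    """Genes dropped while intersecting a pattern with an expression set."""

    dropped_from_pattern: tuple
    dropped_from_expression: tuple
    dropped_missing: tuple


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _default_known_path(path: Path) -> Path:
    return path.with_name(path.stem + ".known" + path.suffix)


def read_connectivity(path, format: str = "matrix-tsv", direction_path=None) -> ConnectivityPattern:
    """Read a connectivity pattern from ``matrix-tsv`` or ``sif-edges``.

    For matrix-TSV, the companion ``direction_known`` mask is read from
    ``direction_path`` (default: ``<stem>.known<suffix>`` next to ``path``)
    when that file exists; otherwise all documented edges are taken as
    direction-known.
    """
    path = Path(path)
    if format == "matrix-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            bad = vals[~np.isin(vals, (-1, 0, 1))][0]
            raise EncodingError(f"connectivity entries must be in {{-1,0,1}}; found {bad!r}")
        known = None
        kpath = Path(direction_path) if direction_path else _default_known_path(path)
        if kpath.exists():
            kdf = pd.read_csv(kpath, sep="\t", index_col=0)
            if list(kdf.index) != list(df.index) or list(kdf.columns) != list(df.columns):
                raise AlignmentError("direction_known companion labels do not match the matrix")
            known = kdf.to_numpy().astype(bool)
        return ConnectivityPattern(tuple(df.index), tuple(df.columns), vals, known)
    if format == "sif-edges":
        rows = pd.read_csv(path, sep="\t", header=None,
                           names=["tf", "relation", "gene"], dtype=str)
        tf_order, gene_order, edges = [], [], {}
        for tf, rel, gene in rows.itertuples(index=False):
            if rel not in _RELATION_TO_ENTRY:
                raise EncodingError(f"unknown relation {rel!r} (expected activates/represses/regulates)")
            if (gene, tf) in edges:
                raise LabelError(f"duplicate edge {tf!r} -> {gene!r} in SIF file")
            if tf not in tf_order:
                tf_order.append(tf)
            if gene not in gene_order:
                gene_order.append(gene)
            edges[(gene, tf)] = (_RELATION_TO_ENTRY[rel], rel != "regulates")
        entries = np.zeros((len(gene_order), len(tf_order)), dtype=np.int8)
        known = np.ones(entries.shape, dtype=bool)
        for (gene, tf), (e, k) in edges.items():
            i, j = gene_order.index(gene), tf_order.index(tf)
            entries[i, j] = e
            known[i, j] = k
        return ConnectivityPattern(tuple(gene_order), tuple(tf_order), entries, known)
    raise ValueError(f"unknown connectivity format {format!r}")


def write_connectivity(pattern: ConnectivityPattern, path, format: str = "matrix-tsv",
                       direction_path=None) -> None:
    """Write a connectivity pattern; inverse of :func:`read_connectivity`.

    Matrix-TSV always writes the ``direction_known`` companion when any edge
    has unknown direction.  SIF output is written gene-major (every gene's
    regulators in pattern order), so reading it back preserves the gene
    order; the TF order is recovered by first appearance.
    """
    path = Path(path)
    if format == "matrix-tsv":
        df = pd.DataFrame(pattern.entries, index=list(pattern.gene_ids),
                          columns=list(pattern.tf_ids))
        df.to_csv(path, sep="\t")
        if not pattern.direction_known[pattern.support].all():
            kpath = Path(direction_path) if direction_path else _default_known_path(path)
            kdf = pd.DataFrame(pattern.direction_known.astype(int),
                               index=list(pattern.gene_ids), columns=list(pattern.tf_ids))
            kdf.to_csv(kpath, sep="\t")
        return
    if format == "sif-edges":
        lines = []
        for i, gene in enumerate(pattern.gene_ids):
            for j, tf in enumerate(pattern.tf_ids):
                e = int(pattern.entries[i, j])
                if e == 0:
                    continue
                rel = _ENTRY_TO_RELATION[(e, bool(pattern.direction_known[i, j]))]
                lines.append(f"{tf}\t{rel}\t{gene}\n")
        path.write_text("".join(lines))
        return
    raise ValueError(f"unknown connectivity format {format!r}")


def read_expression(paths: Sequence) -> ExpressionSet:
    """Read one genes x conditions ratio TSV per biological replicate.

    All files must carry identical gene and condition labels.  A ratio of 1.0
    corresponds to log10 value 0.0 (no change versus control); nonpositive
    values are rejected with their coordinates.
    """
    if not paths:
        raise DomainError("at least one expression file is required")
    frames = [pd.read_csv(Path(p), sep="\t", index_col=0) for p in paths]
    first = frames[0]
    for pth, df in zip(list(paths)[1:], frames[1:]):
        if list(df.index) != list(first.index) or list(df.columns) != list(first.columns):
            raise AlignmentError(f"labels in {pth} do not match the first replicate")
    return ExpressionSet(tuple(first.index), tuple(first.columns),
                         tuple(df.to_numpy(dtype=float) for df in frames))


def write_expression(expr: ExpressionSet, paths: Sequence) -> None:
    """Write one ratio TSV per replicate; inverse of :func:`read_expression`."""
    if len(paths) != expr.n_replicates:
        raise AlignmentError("need one output path per replicate")
    for pth, mat in zip(paths, expr.replicates):
        pd.DataFrame(mat, index=list(expr.gene_ids),
                     columns=list(expr.condition_ids)).to_csv(Path(pth), sep="\t")


def read_tf_expression(paths: Sequence) -> TFExpressionTable:
    """Read ratio TSVs for the genes encoding the TFs (rows = TF genes)."""
    expr_like = read_expression(paths)
    return TFExpressionTable(expr_like.gene_ids, expr_like.condition_ids, expr_like.replicates)


def align(pattern: ConnectivityPattern, expr: ExpressionSet):
    """Restrict a pattern and an expression set to their shared genes.

    The pattern's gene order is preserved.  Genes carrying a missing value in
    any replicate are dropped with a warning (the decomposition has no
    missing-data mechanism).  Returns ``(pattern, expr, AlignReport)``.
    """
    missing = {g for g, bad in zip(expr.gene_ids, expr.has_missing()) if bad}
    if missing:
        warnings.warn(
            f"dropping {len(missing)} gene(s) with missing expression values: "
            + ", ".join(sorted(missing)), stacklevel=2)
    usable = [g for g in expr.gene_ids if g not in missing]
    shared = [g for g in pattern.gene_ids if g in set(usable)]
    if not shared:
        raise AlignmentError("no shared genes between pattern and expression set")
    dropped_pat = tuple(g for g in pattern.gene_ids if g not in set(shared))
    dropped_expr = tuple(g for g in expr.gene_ids if g not in set(shared) and g not in missing)
    new_pattern = pattern.restrict(genes=shared)
    gi = [expr.gene_ids.index(g) for g in shared]
    new_expr = ExpressionSet(tuple(shared), expr.condition_ids,
                             tuple(r[gi, :] for r in expr.replicates))
    return new_pattern, new_expr, AlignReport(dropped_pat, dropped_expr, tuple(sorted(missing)))
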