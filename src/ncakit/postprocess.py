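"""Gauge fixing, sign correction, and replicate aggregation.

The decomposition determines each TF's CS column and activity row only up to
a reciprocal scale (and sign): multiplying a CS column by c and the matching
log TFA row by 1/c leaves the reconstruction unchanged.  The convention here
is root-mean-square 1 over each column's nonzero entries, which makes the
conventional |CS| > 1 threshold for a "strong" interaction read as "above
the column's typical magnitude".

Signs are then anchored on documented edges whose regulatory direction is
experimentally established: if the majority of a TF's anchors carry a fitted
sign opposite to the documented one, the whole column and its activity row
are negated.  Edges curated with unknown direction never act as anchors.

Aggregation pools the best-of-restarts fit from each replicate and reports
element-wise means and sample standard deviations, plus an interaction
classification: strong (|mean CS| > 1 with low run-to-run variability),
weak (0 < |mean CS| <= 1), or undetermined (large but unstable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .decomposition import DecompositionResult
from .exceptions import AggregationError, GaugeError
from .network_model import ConnectivityPattern

DEFAULT_CV_MAX = 0.5

CLASS_LABELS = (
    "strong-activation", "strong-repression",
    "weak-activation", "weak-repression",
    "none", "undetermined",
)


def normalize_gauge(result: DecompositionResult) -> DecompositionResult:
    """Rescale each CS column to RMS 1 over its nonzeros (activity row scaled
    by the reciprocal, so the reconstruction is unchanged)."""
    cs = np.array(result.cs)
    log_tfa = np.array(result.log_tfa)
    for j in range(cs.shape[1]):
        nz = cs[:, j] != 0
        if not nz.any():
            raise GaugeError(f"CS column {j} is all zero; cannot fix its gauge")
        rms = float(np.sqrt(np.mean(cs[nz, j] ** 2)))
        cs[:, j] /= rms
        log_tfa[j, :] *= rms
    return replace(result, cs=cs, log_tfa=log_tfa)


def correct_signs(result: DecompositionResult, pattern: ConnectivityPattern):
    """Resolve the per-TF sign ambiguity against documented edge directions.

    Anchors are the pattern's direction-known edges.  A TF whose anchors
    majority-disagree with the fitted CS signs has its column and activity
    row negated.  Returns ``(corrected_result, flips, unanchored)`` where
    ``flips`` is the per-TF boolean of applied negations and ``unanchored``
    flags TFs left untouched for lack of a majority (no anchors, or an exact
    tie).
    """
    cs = np.array(result.cs)
    log_tfa = np.array(result.log_tfa)
    flips = np.zeros(pattern.p, dtype=bool)
    unanchored = np.zeros(pattern.p, dtype=bool)
    anchors = pattern.support & pattern.direction_known
    for j in range(pattern.p):
        rows = np.flatnonzero(anchors[:, j])
        if rows.size == 0:
            unanchored[j] = True
            continue
        agree = np.sign(cs[rows, j]) == pattern.entries[rows, j]
        n_disagree = int((~agree).sum())
        n_agree = int(agree.sum())
        if n_disagree > n_agree:
            cs[:, j] *= -1.0
            log_tfa[j, :] *= -1.0
            flips[j] = True
        elif n_disagree == n_agree:
            unanchored[j] = True
    return replace(result, cs=cs, log_tfa=log_tfa), flips, unanchored


@dataclass(frozen=True, eq=False)
class AggregateResult:
    """Mean +/- dispersion of CS and log TFA across replicate fits."""

    cs_mean: np.ndarray
    cs_sd: np.ndarray
    tfa_mean: np.ndarray
    tfa_sd: np.ndarray
    classification: np.ndarray  # m x p array of CLASS_LABELS strings
    flips_applied: Optional[np.ndarray] = None
    cv_max: float = DEFAULT_CV_MAX
    n_results: int = 0


def aggregate(results: List[DecompositionResult], pattern: ConnectivityPattern,
              cv_max: float = DEFAULT_CV_MAX,
              flips_applied: Optional[np.ndarray] = None) -> AggregateResult:
    """Pool gauge- and sign-corrected fits into means, dispersions and labels.

    Classification per edge (zero-pattern entries are "none"):

    * ``|mean| > 1`` and coefficient of variation ``|sd/mean| < cv_max`` ->
      strong-activation / strong-repression by the sign of the mean;
    * ``0 < |mean| <= 1`` -> weak-activation / weak-repression;
    * ``|mean| > 1`` but CV >= cv_max -> undetermined.
    """
    if not results:
        raise AggregationError("need at least one decomposition result")
    shapes = {(r.cs.shape, r.log_tfa.shape) for r in results}
    if len(shapes) != 1:
        raise AggregationError(f"results have mismatched dimensions: {shapes}")
    if results[0].cs.shape != (pattern.m, pattern.p):
        raise AggregationError("results do not match the pattern's dimensions")
    cs_stack = np.stack([r.cs for r in results])
    tfa_stack = np.stack([r.log_tfa for r in results])
    cs_mean = cs_stack.mean(axis=0)
    tfa_mean = tfa_stack.mean(axis=0)
    if len(results) > 1:
        cs_sd = cs_stack.std(axis=0, ddof=1)
        tfa_sd = tfa_stack.std(axis=0, ddof=1)
    else:
        cs_sd = np.zeros_like(cs_mean)
        tfa_sd = np.zeros_like(tfa_mean)

    support = np.asarray(pattern.support)
    cs_mean = np.where(support, cs_mean, 0.0)
    absmean = np.abs(cs_mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(absmean > 0, cs_sd / absmean, np.inf)
    classification = np.full(cs_mean.shape, "none", dtype=object)
    weak = support & (absmean > 0) & (absmean <= 1)
    strong = support & (absmean > 1) & (cv < cv_max)
    undet = support & (absmean > 1) & (cv >= cv_max)
    classification[weak & (cs_mean > 0)] = "weak-activation"
    classification[weak & (cs_mean < 0)] = "weak-repression"
    classification[strong & (cs_mean > 0)] = "strong-activation"
    classification[strong & (cs_mean < 0)] = "strong-repression"
    classification[undet] = "undetermined"
    return AggregateResult(
        cs_mean=cs_mean, cs_sd=cs_sd, tfa_mean=tfa_mean, tfa_sd=tfa_sd,
        classification=classification, flips_applied=flips_applied,
        cv_max=cv_max, n_results=len(results))


def export_aggregate(agg: AggregateResult, pattern: ConnectivityPattern,
                     condition_ids: Sequence[str], out_dir) -> dict:
    """Write the aggregate as TSVs plus a CS-weighted edge list.

    Emits cs_mean.tsv, cs_sd.tsv, tfa_mean.tsv, tfa_sd.tsv,
    classification.tsv, and edges.tsv
    (``tf  gene  cs_mean  cs_sd  class``) for network viewers.
    Returns the mapping of artifact name to path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes, tfs = list(pattern.gene_ids), list(pattern.tf_ids)
    conds = list(condition_ids)
    paths = {}
    for name, mat, idx, cols in (
        ("cs_mean", agg.cs_mean, genes, tfs),
        ("cs_sd", agg.cs_sd, genes, tfs),
        ("tfa_mean", agg.tfa_mean, tfs, conds),
        ("tfa_sd", agg.tfa_sd, tfs, conds),
        ("classification", agg.classification, genes, tfs),
    ):
        p = out_dir / f"{name}.tsv"
        pd.DataFrame(mat, index=idx, columns=cols).to_csv(p, sep="\t")
        paths[name] = p
    rows = []
    support = np.asarray(pattern.support)
    for i, g in enumerate(genes):
        for j, t in enumerate(tfs):
            if support[i, j]:
                rows.append((t, g, agg.cs_mean[i, j], agg.cs_sd[i, j],
                             agg.classification[i, j]))
    edges = pd.DataFrame(rows, columns=["tf", "gene", "cs_mean", "cs_sd", "class"])
    p = out_dir / "edges.tsv"
    edges.to_csv(p, sep="\t", index=False)
    paths["edges"] = p
    return paths
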