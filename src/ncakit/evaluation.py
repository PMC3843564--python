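"""Evaluation of a fitted model against measured expression and TF mRNA.

Three complementary views:

* reconstruction — the model-simulated log expression (CS . log TFA) pooled
  into a single scatter against the measurements, summarised by the global
  coefficient of determination R^2 = 1 - SS_res / SS_tot about the grand
  mean of the measured values (replicates are averaged per gene x condition
  before comparison);
* activity-versus-transcript parity — each TF's inferred activity profile
  across conditions, min-max normalized to [0, 1], against the equally
  normalized log10 expression profile of the gene encoding that TF.
  Agreement suggests the activity tracks the transcript; disagreement is a
  lead on post-transcriptional or post-translational control.  Composite
  regulators (an obligate dimer written "A/B") are compared against each
  constituent gene separately;
* pairwise condition contrasts — for every unordered pair of conditions, a
  two-sided Welch (unequal-variance) t test on the replicate activities,
  flagged at a strict p < alpha cutoff with no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlignmentError,
    DegenerateVarianceError,
    DimensionError,
    DomainError,
    InsufficientReplicationError,
)
from .network_model import TFExpressionTable

DEFAULT_ALPHA = 0.05


def simulate_expression(cs: np.ndarray, log_tfa: np.ndarray) -> np.ndarray:
    """Model-simulated log10 expression: the plain product CS . log TFA."""
    cs = np.asarray(cs, dtype=float)
    log_tfa = np.asarray(log_tfa, dtype=float)
    if cs.ndim != 2 or log_tfa.ndim != 2 or cs.shape[1] != log_tfa.shape[0]:
        raise DimensionError(
            f"cannot multiply CS {cs.shape} by log TFA {log_tfa.shape}")
    return cs @ log_tfa


def reconstruction_r2(measured: Union[np.ndarray, Sequence[np.ndarray]],
                      simulated: np.ndarray) -> float:
    """Pooled R^2 between measured and simulated log expression.

    ``measured`` may be a single m x n log matrix or a sequence of replicate
    matrices (averaged per gene x condition first).  SS_tot is taken about
    the grand mean of the measured values, so a simulation equal to that
    grand mean scores exactly 0 and a perfect fit scores 1.
    """
    if isinstance(measured, (list, tuple)):
        measured = np.mean([np.asarray(r, dtype=float) for r in measured], axis=0)
    measured = np.asarray(measured, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if measured.shape != simulated.shape:
        raise DimensionError(
            f"measured {measured.shape} and simulated {simulated.shape} differ")
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateVarianceError("measured matrix has zero total variance")
    ss_res = float(np.sum((measured - simulated) ** 2))
    return 1.0 - ss_res / ss_tot


def minmax_normalize(series: np.ndarray):
    """Map a condition series affinely onto [0, 1] via (x - min)/(max - min).

    A constant series has no range to normalize by; it returns all 0.5 with
    ``degenerate=True`` so parity plots can still render a flat profile.
    Returns ``(normalized, degenerate)``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise DomainError("minmax_normalize needs a 1-D series of length >= 2")
    lo, hi = float(series.min()), float(series.max())
    if hi == lo:
        return np.full(series.shape, 0.5), True
    return (series - lo) / (hi - lo), False


@dataclass(frozen=True)
class ParityEntry:
    """One TF-versus-encoding-gene comparison across conditions."""

    tf: str
    gene: str
    norm_tfa: np.ndarray
    norm_mrna: np.ndarray
    pearson_r: float           # NaN when either series is constant
    tfa_degenerate: bool
    mrna_degenerate: bool


def tfa_mrna_parity(tfa_mean: np.ndarray, tf_ids: Sequence[str],
                    tf_expr: TFExpressionTable) -> List[ParityEntry]:
    """Compare normalized activity profiles against normalized mRNA profiles.

    ``tfa_mean`` rows (log10 fold activity vs control) follow ``tf_ids``;
    mRNA ratios are log10-transformed and averaged over replicates before
    normalization.  A composite regulator label "A/B" is matched against
    each constituent gene's series separately.
    """
    tfa_mean = np.asarray(tfa_mean, dtype=float)
    if tfa_mean.shape != (len(tf_ids), len(tf_expr.condition_ids)):
        raise DimensionError("tfa_mean shape does not match tf_ids x conditions")
    mrna_log = tf_expr.mean_log()
    out = []
    for i, tf in enumerate(tf_ids):
        constituents = tf.split("/") if "/" in tf else [tf]
        for gene in constituents:
            if gene not in tf_expr.tf_ids:
                raise AlignmentError(
                    f"no expression series for TF-encoding gene {gene!r}")
            row = tf_expr.tf_ids.index(gene)
            norm_tfa, deg_a = minmax_normalize(tfa_mean[i])
            norm_mrna, deg_m = minmax_normalize(mrna_log[row])
            if deg_a or deg_m:
                r = float("nan")
            else:
                r = float(stats.pearsonr(norm_tfa, norm_mrna).statistic)
            out.append(ParityEntry(tf, gene, norm_tfa, norm_mrna, r, deg_a, deg_m))
    return out


def pairwise_condition_test(tfa_stack: np.ndarray, tf_ids: Sequence[str],
                            condition_ids: Sequence[str],
                            alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Welch t tests of activity between every unordered condition pair.

    ``tfa_stack`` holds the per-replicate activity matrices, shape
    (n_replicates, p, n).  Significance uses the strict inequality
    ``p < alpha`` with no multiple-testing correction.  Two identical
    samples give t = 0 and p = 1; two zero-variance samples are compared by
    their means alone (p = 1 if equal, else 0).
    """
    tfa_stack = np.asarray(tfa_stack, dtype=float)
    if tfa_stack.ndim != 3 or tfa_stack.shape[1:] != (len(tf_ids), len(condition_ids)):
        raise DimensionError("tfa_stack must have shape (replicates, p, n)")
    if tfa_stack.shape[0] < 2:
        raise InsufficientReplicationError(
            "pairwise condition tests need at least 2 replicate fits per condition")
    rows = []
    for i, tf in enumerate(tf_ids):
        for a, b in combinations(range(len(condition_ids)), 2):
            xa, xb = tfa_stack[:, i, a], tfa_stack[:, i, b]
            if np.ptp(xa) == 0 and np.ptp(xb) == 0:
                equal = xa[0] == xb[0]
                t, p = (0.0, 1.0) if equal else (np.inf, 0.0)
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=False)
                t, p = float(t), float(p)
            rows.append((tf, condition_ids[a], condition_ids[b], t, p, p < alpha))
    return pd.DataFrame(rows, columns=["tf", "condition_a", "condition_b",
                                       "t", "p", "significant"])


@dataclass(frozen=True, eq=False)
class EvaluationReport:
    """Reconstruction, parity and contrast statistics for one fitted model."""

    r_squared: float
    parity: tuple                     # of ParityEntry
    pairwise_tests: Optional[pd.DataFrame]
    alpha: float
    measured_log: np.ndarray
    simulated_log: np.ndarray

    def parity_frame(self, condition_ids: Sequence[str]) -> pd.DataFrame:
        rows = []
        for e in self.parity:
            for c, ta, mr in zip(condition_ids, e.norm_tfa, e.norm_mrna):
                rows.append((e.tf, e.gene, c, ta, mr, e.pearson_r,
                             e.tfa_degenerate, e.mrna_degenerate))
        return pd.DataFrame(rows, columns=[
            "tf", "gene", "condition", "norm_tfa", "norm_mrna",
            "pearson_r", "tfa_degenerate", "mrna_degenerate"])


def evaluate(measured, cs, log_tfa, tf_ids, condition_ids,
             tf_expr: Optional[TFExpressionTable] = None,
             tfa_stack: Optional[np.ndarray] = None,
             alpha: float = DEFAULT_ALPHA) -> EvaluationReport:
    """Assemble the full evaluation report for a fitted model."""
    simulated = simulate_expression(cs, log_tfa)
    r2 = reconstruction_r2(measured, simulated)
    if isinstance(measured, (list, tuple)):
        measured = np.mean([np.asarray(r, dtype=float) for r in measured], axis=0)
    parity = ()
    if tf_expr is not None:
        if tuple(tf_expr.condition_ids) != tuple(condition_ids):
            raise AlignmentError("TF-expression condition labels do not match the fit")
        parity = tuple(tfa_mrna_parity(log_tfa, tf_ids, tf_expr))
    tests = None
    if tfa_stack is not None:
        tests = pairwise_condition_test(tfa_stack, tf_ids, condition_ids, alpha)
    return EvaluationReport(r_squared=r2, parity=parity, pairwise_tests=tests,
                            alpha=alpha, measured_log=np.asarray(measured, float),
                            simulated_log=simulated)


def export_evaluation(report: EvaluationReport, gene_ids, condition_ids, out_dir) -> dict:
    """Write parity.tsv, pairwise_tests.tsv and scatter.tsv (measured vs
    simulated log expression pairs) for external plotting."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if report.parity:
        p = out_dir / "parity.tsv"
        report.parity_frame(condition_ids).to_csv(p, sep="\t", index=False)
        paths["parity"] = p
    if report.pairwise_tests is not None:
        p = out_dir / "pairwise_tests.tsv"
        report.pairwise_tests.to_csv(p, sep="\t", index=False)
        paths["pairwise_tests"] = p
    rows = []
    for i, g in enumerate(gene_ids):
        for j, c in enumerate(condition_ids):
            rows.append((g, c, report.measured_log[i, j], report.simulated_log[i, j]))
    scat = pd.DataFrame(rows, columns=["gene", "condition", "measured_log10",
                                       "simulated_log10"])
    p = out_dir / "scatter.tsv"
    scat.to_csv(p, sep="\t", index=False)
    paths["scatter"] = p
    with open(out_dir / "r_squared.txt", "w") as fh:
        fh.write(f"{report.r_squared}\n")
    paths["r_squared"] = out_dir / "r_squared.txt"
    return paths
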