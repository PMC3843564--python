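"""Constrained bilinear decomposition of log expression: log G = CS . log TFA.

The fit is a two-step (alternating) least squares on the squared Frobenius
residual, honouring the zero pattern of the connectivity prior exactly:

* CS-step — with log TFA fixed, each gene's row decouples into an ordinary
  least-squares problem over its own regulators only (k_i unknowns against
  n condition equations; feasible whenever in-degree <= n);
* TFA-step — with CS fixed, each condition's column decouples into a
  least-squares problem for the p activities (p unknowns against m gene
  equations; overdetermined because m >> p).

Each half-step is an exact minimizer of the objective given the other
block, so the objective is non-increasing at every half-step.  The
decomposition is identifiable only up to one scale (and sign) per TF; the
gauge is fixed afterwards in :mod:`ncakit.postprocess`.

Because the objective is biconvex but not convex, the solver runs several
seeded random restarts and returns the best final objective.  Run-to-run
variability across restarts is a real feature of this estimator and is
surfaced, not hidden: per-iteration objective traces and the restart index
are kept on the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .compliance import check_compliance
from .exceptions import ComplianceError, DimensionError, RankDeficiencyError
from .network_model import ConnectivityPattern, ExpressionSet

DEFAULT_MAX_ITER = 1000
DEFAULT_TOL = 1e-9
DEFAULT_RESTARTS = 10


@dataclass(frozen=True, eq=False)
class DecompositionResult:
    """Fitted CS (m x p) and log10 TFA (p x n) with convergence metadata.

    ``cs`` is exactly zero wherever the connectivity pattern is zero.
    ``objective`` is the final squared Frobenius residual
    ``|| cs . log_tfa - log_g ||_F**2``; ``objective_trace`` records the
    objective after every half-step (starting from the initial state), and
    is non-increasing.
    """

    cs: np.ndarray
    log_tfa: np.ndarray
    objective: float
    n_iterations: int
    converged: bool
    seed: int
    restart_index: int
    objective_trace: np.ndarray

    def reconstruction(self) -> np.ndarray:
        """Model-simulated log10 expression, CS . log TFA."""
        return self.cs @ self.log_tfa


def _regulator_groups(support: np.ndarray):
    """Group genes by in-degree for batched CS-step solves.

    Returns a list of ``(gene_indices, tf_indices)`` with ``tf_indices`` of
    shape (n_genes_in_group, k).  Genes without regulators are omitted
    (their CS row stays zero).
    """
    in_deg = support.sum(axis=1)
    groups = []
    for k in np.unique(in_deg):
        if k == 0:
            continue
        genes = np.flatnonzero(in_deg == k)
        tf_idx = np.vstack([np.flatnonzero(support[g]) for g in genes])
        groups.append((genes, tf_idx))
    return groups


def _als_run(log_g: np.ndarray, groups, m: int, p: int, rng: np.random.Generator,
             max_iter: int, tol: float):
    """One ALS run from a random activity initialization."""
    n = log_g.shape[1]
    log_tfa = rng.uniform(-1.0, 1.0, size=(p, n))
    cs = np.zeros((m, p))
    sq = float(np.sum(log_g * log_g))
    trace = [sq]  # objective with cs = 0
    prev = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # CS-step: per-gene OLS restricted to the gene's regulators
        for genes, tf_idx in groups:
            A = log_tfa[tf_idx]                              # (g, k, n)
            M = np.einsum("gkn,gln->gkl", A, A)              # normal matrices
            b = np.einsum("gkn,gn->gk", A, log_g[genes])
            try:
                x = np.linalg.solve(M, b[..., None])[..., 0]
            except np.linalg.LinAlgError:
                dets = np.abs(np.linalg.det(M))
                bad = genes[int(np.argmin(dets))]
                raise RankDeficiencyError(
                    f"collinear regulator activities for gene index {bad}"
                ) from None
            cs[genes[:, None], tf_idx] = x
        resid = cs @ log_tfa - log_g
        obj = float(np.sum(resid * resid))
        trace.append(obj)
        # TFA-step: all conditions at once (columns decouple)
        log_tfa = np.linalg.lstsq(cs, log_g, rcond=None)[0]
        resid = cs @ log_tfa - log_g
        obj = float(np.sum(resid * resid))
        trace.append(obj)
        if prev is not None and prev - obj <= tol * max(prev, np.finfo(float).tiny):
            converged = True
            break
        prev = obj
    return cs, log_tfa, trace[-1], it, converged, np.asarray(trace)


def decompose(log_g: np.ndarray, pattern: ConnectivityPattern, seed: int,
              max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL,
              n_restarts: int = DEFAULT_RESTARTS,
              check: bool = True) -> DecompositionResult:
    """Fit CS and log TFA to one replicate's log10 expression matrix.

    Parameters
    ----------
    log_g
        m x n log10 expression ratios (m must match the pattern).
    pattern
        Connectivity prior; must be NCA-compliant (checked unless
        ``check=False``, e.g. when the caller already holds a report).
    seed
        Seeds the random activity initializations; restart ``r`` uses the
        independent stream ``(seed, r)``.
    max_iter, tol
        Iteration cap and relative objective-change convergence threshold.
    n_restarts
        Number of random restarts; the best final objective wins
        (ties broken by lowest restart index).
    """
    log_g = np.asarray(log_g, dtype=float)
    if log_g.ndim != 2 or log_g.shape[0] != pattern.m:
        raise DimensionError(
            f"log_g shape {log_g.shape} does not match pattern with m={pattern.m}")
    if np.isnan(log_g).any():
        raise DimensionError("log_g contains missing values; align/drop them first")
    n = log_g.shape[1]
    if check:
        report = check_compliance(pattern, n, seed=0)
        if not report.compliant:
            raise ComplianceError(
                "pattern is not NCA-compliant for this dataset; "
                f"offending TFs: {list(report.offending_tfs)}, "
                f"offending genes: {list(report.offending_genes)}")
    groups = _regulator_groups(np.asarray(pattern.support))
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng((abs(int(seed)), r))
        try:
            cs, log_tfa, obj, iters, conv, trace = _als_run(
                log_g, groups, pattern.m, pattern.p, rng, max_iter, tol)
        except RankDeficiencyError as err:
            # name the gene, not just its index
            idx = int(str(err).rsplit(" ", 1)[-1])
            raise RankDeficiencyError(
                f"collinear regulator activities for gene {pattern.gene_ids[idx]!r}"
            ) from None
        if best is None or obj < best.objective:
            best = DecompositionResult(
                cs=cs, log_tfa=log_tfa, objective=obj, n_iterations=iters,
                converged=conv, seed=int(seed), restart_index=r,
                objective_trace=trace)
    return best


def decompose_replicates(expr: ExpressionSet, pattern: ConnectivityPattern,
                         seed: int, max_iter: int = DEFAULT_MAX_ITER,
                         tol: float = DEFAULT_TOL,
                         n_restarts: int = DEFAULT_RESTARTS) -> List[DecompositionResult]:
    """Fit each biological replicate independently (replicate r seeds with seed + r).

    The expression set must already be aligned to the pattern (same genes in
    the same order).
    """
    if expr.gene_ids != pattern.gene_ids:
        raise DimensionError("expression set is not aligned to the pattern; call align() first")
    report = check_compliance(pattern, expr.n, seed=0)
    if not report.compliant:
        raise ComplianceError(
            "pattern is not NCA-compliant for this dataset; "
            f"offending TFs: {list(report.offending_tfs)}, "
            f"offending genes: {list(report.offending_genes)}")
    return [
        decompose(lg, pattern, seed=seed + r, max_iter=max_iter, tol=tol,
                  n_restarts=n_restarts, check=False)
        for r, lg in enumerate(expr.log_ratios())
    ]
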