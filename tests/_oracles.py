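"""Independent oracles used by the test suite.

Deliberately written without reference to the package's own code paths:
symbolic ranks go through sympy's exact arithmetic, the grid search scans a
lattice, and the Welch statistic is the closed-form textbook formula.
"""

import math

import numpy as np
import sympy
from scipy.special import stdtr


def symbolic_generic_rank(entries) -> int:
    """Exact structural rank: rank over the rational function field with one
    independent symbol per nonzero entry (equivalent to exhaustive minor
    expansion)."""
    entries = np.asarray(entries)
    m, p = entries.shape
    if m == 0 or p == 0:
        return 0
    M = sympy.zeros(m, p)
    k = 0
    for i in range(m):
        for j in range(p):
            if entries[i, j] != 0:
                M[i, j] = sympy.Symbol(f"x{k}")
                k += 1
    return int(M.rank())


def oracle_compliance(entries, n_conditions: int) -> dict:
    """Re-derive the identifiability decision from scratch, symbolically."""
    entries = np.asarray(entries)
    m, p = entries.shape
    support = entries != 0
    c1 = symbolic_generic_rank(entries) == p
    c2 = []
    for l in range(p):
        rows = np.flatnonzero(~support[:, l])
        cols = [j for j in range(p) if j != l]
        sub = entries[np.ix_(rows, cols)]
        rank = symbolic_generic_rank(sub) if sub.size else 0
        c2.append(rank == p - 1)
    in_deg = support.sum(axis=1)
    reg = support.sum(axis=0)
    limited = bool((in_deg <= n_conditions).all() and (reg >= 2).all())
    return {
        "criterion1_ok": bool(c1),
        "criterion2_ok": [bool(x) for x in c2],
        "limited_data_ok": limited,
        "compliant": bool(c1 and all(c2) and limited),
    }


def grid_search_min_objective(log_g, support, step: float = 0.05,
                              bound: float = 2.0, chunk: int = 250_000) -> float:
    """Lattice lower envelope for the bilinear fit.

    The per-TF scaling gauge lets each CS column's first nonzero be fixed to
    +/-1 without loss of generality; the remaining nonzero CS entries scan a
    lattice of the given step over [-bound, bound], and for each candidate CS
    the activities are profiled out exactly by least squares.  Returns the
    smallest objective found (an upper bound on the global minimum).
    """
    log_g = np.asarray(log_g, dtype=float)
    support = np.asarray(support, dtype=bool)
    m, p = support.shape
    cols = [np.flatnonzero(support[:, j]) for j in range(p)]
    first = [c[0] for c in cols]
    free = [(i, j) for j in range(p) for i in cols[j][1:]]
    lattice = np.arange(-bound, bound + step / 2, step)
    axes = [np.array([-1.0, 1.0])] * p + [lattice] * len(free)
    grids = np.meshgrid(*axes, indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=1)
    yty = float(np.sum(log_g * log_g))
    best = np.inf
    for start in range(0, combos.shape[0], chunk):
        c = combos[start:start + chunk]
        B = c.shape[0]
        CS = np.zeros((B, m, p))
        for j in range(p):
            CS[:, first[j], j] = c[:, j]
        for t, (i, j) in enumerate(free):
            CS[:, i, j] = c[:, p + t]
        G = np.einsum("bmp,bmq->bpq", CS, CS)
        E = np.einsum("bmp,mn->bpn", CS, log_g)
        dets = np.linalg.det(G)
        ok = np.abs(dets) > 1e-12
        if not ok.any():
            continue
        X = np.linalg.solve(G[ok], E[ok])
        objs = yty - np.einsum("bpn,bpn->b", E[ok], X)
        best = min(best, float(objs.min()))
    return best


def welch_t_p(x, y):
    """Closed-form Welch t statistic and two-sided p value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stdtr(df, -abs(t))
    return t, p


def two_pass_mean_sd(stack):
    """Brute-force element-wise mean and sample SD over a list of matrices."""
    stack = [np.asarray(a, float) for a in stack]
    k = len(stack)
    mean = sum(stack) / k
    if k == 1:
        return mean, np.zeros_like(mean)
    var = sum((a - mean) ** 2 for a in stack) / (k - 1)
    return mean, np.sqrt(var)


def pooled_r2_textbook(measured, simulated) -> float:
    """R^2 as 1 - SSE/SST about the grand mean, via explicit loops."""
    measured = np.asarray(measured, float)
    simulated = np.asarray(simulated, float)
    grand = measured.sum() / measured.size
    sse = sst = 0.0
    for i in range(measured.shape[0]):
        for j in range(measured.shape[1]):
            sse += (measured[i, j] - simulated[i, j]) ** 2
            sst += (measured[i, j] - grand) ** 2
    return 1.0 - sse / sst


def triple_loop_product(cs, log_tfa):
    """Naive matrix product for simulate_expression cross-checks."""
    cs = np.asarray(cs, float)
    log_tfa = np.asarray(log_tfa, float)
    m, p = cs.shape
    n = log_tfa.shape[1]
    out = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            for k in range(p):
                out[i, j] += cs[i, k] * log_tfa[k, j]
    return out
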