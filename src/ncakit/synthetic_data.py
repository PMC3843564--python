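"""Synthetic ground truth for end-to-end testing of the decomposition.

The generator emulates the statistical structure the analysis assumes: a
sparse signed bipartite connectivity pattern over a handful of TFs and a few
dozen genes, condition-wise activity fold changes, and ratio-to-control
expression built as 10**(CS . log TFA + noise) with additive Gaussian noise
in log10 space (i.e. multiplicative log-normal noise on the ratios, the
standard error model for ratio microarray data).

Defaults mirror the floral study's scale: ~50-60 genes, 7 TFs, 4
conditions, 2-3 replicates, noise sigma 0.05 log10 units.  What the
generator deliberately does not emulate: probe-level artifacts, batch
effects, missingness, or feedback between TFs.

:func:`floral_fixture` builds the small floral-development network that can
be reconstructed verbatim from the study's running text (not its
supplementary connectivity matrix): LFY and six further regulators over 27
target genes, including AGL15's four documented-but-undirected edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .compliance import check_compliance
from .exceptions import InfeasibleParametersError
from .network_model import (
    ConnectivityPattern,
    ExpressionSet,
    write_connectivity,
    write_expression,
)

DEFAULT_NOISE_SD = 0.05     # log10 units
DEFAULT_TFA_SCALE = 0.5     # spread of log10 activity fold changes
DEFAULT_REPLICATES = 3
DEFAULT_CS_MIN = 0.2        # lower bound on |CS| before gauge normalization


@dataclass(frozen=True, eq=False)
class SyntheticTruth:
    """A generating model: pattern, gauge-normalized CS, activities, noise."""

    pattern: ConnectivityPattern
    cs_true: np.ndarray        # m x p, RMS 1 per column's nonzeros, signs match pattern
    log_tfa_true: np.ndarray   # p x n, log10 fold activity vs control
    condition_ids: tuple
    noise_sd: float
    n_replicates: int
    seed: int


def generate_pattern(m: int, p: int, targets_per_tf: Tuple[int, int] = (2, 12),
                     repression_fraction: float = 0.3, n_conditions: int = 4,
                     seed: int = 0, max_in_degree: Optional[int] = None,
                     max_tries: int = 1000) -> ConnectivityPattern:
    """Rejection-sample a random signed bipartite pattern until compliant.

    Regulon sizes are drawn uniformly from ``targets_per_tf``; each edge is a
    repression with probability ``repression_fraction``.  Gene in-degrees are
    capped at ``max_in_degree`` (default: ``n_conditions``, the regression
    feasibility bound) and every gene is guaranteed at least one regulator.
    Deterministic given ``seed``.
    """
    lo, hi = targets_per_tf
    if m < 2 * p or lo < 2:
        raise InfeasibleParametersError(
            "need m >= 2p and at least 2 targets per TF for a compliant pattern")
    cap = min(max_in_degree or n_conditions, n_conditions)
    rng = np.random.default_rng(abs(int(seed)))
    for _ in range(max_tries):
        E = np.zeros((m, p), dtype=np.int8)
        for j in range(p):
            size = int(rng.integers(lo, hi + 1))
            targets = rng.choice(m, size=size, replace=False)
            signs = np.where(rng.random(size) < repression_fraction, -1, 1)
            E[targets, j] = signs
        # enforce the in-degree cap by trimming random regulators
        for i in np.flatnonzero((E != 0).sum(axis=1) > cap):
            regs = np.flatnonzero(E[i])
            drop = rng.choice(regs, size=regs.size - cap, replace=False)
            E[i, drop] = 0
        # guarantee every gene at least one regulator
        for i in np.flatnonzero((E != 0).sum(axis=1) == 0):
            j = int(rng.integers(p))
            E[i, j] = -1 if rng.random() < repression_fraction else 1
        if ((E != 0).sum(axis=0) < 2).any():
            continue
        pattern = ConnectivityPattern(
            tuple(f"G{i + 1:03d}" for i in range(m)),
            tuple(f"TF{j + 1}" for j in range(p)), E)
        if check_compliance(pattern, n_conditions, seed=seed).compliant:
            return pattern
    raise InfeasibleParametersError(
        f"no compliant pattern found in {max_tries} draws for m={m}, p={p}, "
        f"targets {targets_per_tf}, n={n_conditions}")


def generate_truth(pattern: ConnectivityPattern, tfa_scale: float = DEFAULT_TFA_SCALE,
                   cs_shape: float = 2.0, n_conditions: int = 4, seed: int = 0,
                   noise_sd: float = DEFAULT_NOISE_SD,
                   n_replicates: int = DEFAULT_REPLICATES,
                   cs_min: float = DEFAULT_CS_MIN) -> SyntheticTruth:
    """Draw ground-truth CS and activities consistent with ``pattern``.

    Nonzero |CS| magnitudes are ``cs_min`` plus a Gamma(cs_shape) draw with
    unit-mean scale — continuous and bounded away from zero, so no edge is
    unidentifiably weak — then each column is gauge-normalized to RMS 1 over
    its nonzeros.  Activities are i.i.d. Normal(0, tfa_scale^2) in log10
    units (``tfa_scale=0`` makes every condition equal the control).
    """
    rng = np.random.default_rng(abs(int(seed)))
    m, p = pattern.m, pattern.p
    support = np.asarray(pattern.support)
    mags = cs_min + rng.gamma(cs_shape, 1.0 / cs_shape, size=(m, p))
    cs = np.where(support, mags * pattern.entries, 0.0)
    for j in range(p):
        nz = support[:, j]
        cs[:, j] /= np.sqrt(np.mean(cs[nz, j] ** 2))
    if tfa_scale == 0:
        log_tfa = np.zeros((p, n_conditions))
    else:
        log_tfa = rng.normal(0.0, tfa_scale, size=(p, n_conditions))
    return SyntheticTruth(
        pattern=pattern, cs_true=cs, log_tfa_true=log_tfa,
        condition_ids=tuple(f"C{j + 1}" for j in range(n_conditions)),
        noise_sd=float(noise_sd), n_replicates=int(n_replicates),
        seed=abs(int(seed)))


def simulate_replicates(truth: SyntheticTruth) -> ExpressionSet:
    """Emit noisy replicate expression ratios from a generating truth.

    Each replicate is 10**(CS . log TFA + eps) with eps i.i.d.
    Normal(0, noise_sd^2) in log10 space; ratios are therefore strictly
    positive and log-normal around the noiseless model.  Deterministic given
    ``truth.seed`` (replicate r uses the stream (seed, 1000 + r)).
    """
    clean = truth.cs_true @ truth.log_tfa_true
    reps = []
    for r in range(truth.n_replicates):
        rng = np.random.default_rng((truth.seed, 1000 + r))
        noise = rng.normal(0.0, truth.noise_sd, size=clean.shape) if truth.noise_sd else 0.0
        reps.append(10.0 ** (clean + noise))
    return ExpressionSet(truth.pattern.gene_ids, truth.condition_ids, tuple(reps))


# ---------------------------------------------------------------------------
# the in-text floral network
# ---------------------------------------------------------------------------

_FLORAL_EDGES = [
    # (tf, gene, entry, direction_known)
    *[("LFY", g, 1, True) for g in
      ("ACR7", "HB51", "GRA1", "UNK3", "MYB17", "TLP8",
       "ASN1", "BGLU15", "BZIP", "LEA", "UNK2", "SUS4")],
    ("AG", "CRC", 1, True),
    ("SEP3", "AGL4", 1, True),
    ("SEP3", "AGL3", 1, True),
    ("SEP3", "AGL8", 1, True),
    ("SEP3", "AGL22", 1, True),
    ("AP2", "HLH1", -1, True),
    ("AP2", "RD20", -1, True),
    ("AGL15", "AGL22", 1, False),
    ("AGL15", "LEA7", 1, True),
    ("AGL15", "RAV2", 1, False),
    ("AGL15", "CSP4", 1, True),
    ("AGL15", "CBF2", 1, True),
    ("AGL15", "AGL25", 1, False),
    ("AGL15", "EDF4", 1, False),
    ("HY5", "HLH1", 1, True),
    ("HY5", "RAV2", 1, True),
    ("HY5", "RD20", 1, True),
    ("HY5", "UNK4", 1, True),
    ("AP3/PI", "FLO10", 1, True),
]


def floral_fixture() -> Tuple[ConnectivityPattern, pd.DataFrame]:
    """The partial floral-development network stated in the study's text.

    Seven regulators (LFY, AG, SEP3, AP2, AGL15, HY5 and the AP3/PI dimer)
    over 27 target genes.  HY5 activates and AP2 represses the co-regulated
    HLH1 and RD20; AGL15's edges to AGL22, AGL25, EDF4 and RAV2 are
    documented without a direction and carry ``direction_known=False``.
    Edges whose direction the text does not state are encoded as documented
    activations.  This is deliberately NOT a reconstruction of the study's
    full curated connectivity matrix, only of the edges its prose names.

    Returns the pattern and the documented-edge table
    (``tf  gene  entry  direction_known``).
    """
    tf_order, gene_order = [], []
    for tf, gene, _, _ in _FLORAL_EDGES:
        if tf not in tf_order:
            tf_order.append(tf)
        if gene not in gene_order:
            gene_order.append(gene)
    entries = np.zeros((len(gene_order), len(tf_order)), dtype=np.int8)
    known = np.ones(entries.shape, dtype=bool)
    for tf, gene, e, k in _FLORAL_EDGES:
        i, j = gene_order.index(gene), tf_order.index(tf)
        entries[i, j] = e
        known[i, j] = k
    pattern = ConnectivityPattern(tuple(gene_order), tuple(tf_order), entries, known)
    table = pd.DataFrame(_FLORAL_EDGES, columns=["tf", "gene", "entry", "direction_known"])
    return pattern, table


# ---------------------------------------------------------------------------
# reproducible study directories
# ---------------------------------------------------------------------------

def make_dataset(out_dir, m: int = 55, p: int = 7, n_conditions: int = 4,
                 n_replicates: int = DEFAULT_REPLICATES,
                 noise_sd: float = DEFAULT_NOISE_SD,
                 tfa_scale: float = DEFAULT_TFA_SCALE,
                 targets_per_tf: Tuple[int, int] = (2, 12),
                 repression_fraction: float = 0.3, seed: int = 0) -> dict:
    """Materialize a reproducible synthetic study directory.

    Writes pattern.tsv (+ direction companion when needed), cs_true.tsv,
    log_tfa_true.tsv, one replicate_<r>.tsv per replicate, and a
    manifest.json echoing every parameter and the seed.  Returns the
    manifest dictionary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pattern = generate_pattern(m, p, targets_per_tf, repression_fraction,
                               n_conditions, seed)
    truth = generate_truth(pattern, tfa_scale=tfa_scale, n_conditions=n_conditions,
                           seed=seed, noise_sd=noise_sd, n_replicates=n_replicates)
    expr = simulate_replicates(truth)
    write_connectivity(pattern, out_dir / "pattern.tsv", "matrix-tsv")
    pd.DataFrame(truth.cs_true, index=list(pattern.gene_ids),
                 columns=list(pattern.tf_ids)).to_csv(out_dir / "cs_true.tsv", sep="\t")
    pd.DataFrame(truth.log_tfa_true, index=list(pattern.tf_ids),
                 columns=list(truth.condition_ids)).to_csv(
        out_dir / "log_tfa_true.tsv", sep="\t")
    rep_paths = [out_dir / f"replicate_{r}.tsv" for r in range(n_replicates)]
    write_expression(expr, rep_paths)
    manifest = {
        "kind": "synthetic-study",
        "seed": int(seed),
        "m": m, "p": p, "n_conditions": n_conditions,
        "n_replicates": n_replicates, "noise_sd": noise_sd,
        "tfa_scale": tfa_scale, "targets_per_tf": list(targets_per_tf),
        "repression_fraction": repression_fraction,
        "files": {
            "pattern": "pattern.tsv",
            "cs_true": "cs_true.tsv",
            "log_tfa_true": "log_tfa_true.tsv",
            "replicates": [p.name for p in rep_paths],
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
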