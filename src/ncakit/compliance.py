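"""Structural identifiability ("NCA-compliance") checks and network pruning.

The bilinear decomposition log G = CS . log TFA is unique up to one scale
factor per TF only when the connectivity pattern satisfies rank conditions:

* criterion 1 — the pattern has generic (structural) column rank p;
* criterion 2 — for every TF l, the submatrix over the genes NOT regulated
  by l and the remaining p-1 TF columns has generic rank p-1 (no TF's
  regulon may be structurally redundant given the others; in particular a
  regulon nested inside another TF's regulon fails this test);
* criterion 3 — the original algorithm's data-dimension sufficiency
  n_conditions >= p.  Networks fitted from few conditions (the limited-data
  regime) can violate criterion 3 and still be solvable provided every
  per-gene regression is determined: in-degree <= n_conditions for every
  gene, and every TF regulates at least two genes.

Generic rank is evaluated numerically: each nonzero entry is replaced by an
independent continuous draw bounded away from zero and the numerical rank is
taken; the maximum over a few trials equals the structural rank with
probability one.  A symbolic oracle pins this down on small instances in the
test suite.

Pruning removes, in order: genes that encode a retained TF (the model cannot
express a TF regulating its own transcript), genes whose in-degree exceeds
the number of conditions, and then greedily the TF with the smallest regulon
among those violating the two-target rule or implicated in a rank
deficiency (lexicographic tie-break), dropping genes orphaned by each TF
removal, until the pattern is compliant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .exceptions import DimensionError, InfeasiblePruneError
from .network_model import ConnectivityPattern

DEFAULT_TRIALS = 5


# ---------------------------------------------------------------------------
# generic (structural) rank
# ---------------------------------------------------------------------------

def _generic_rank_raw(entries: np.ndarray, trials: int, seed: int) -> int:
    if entries.size == 0:
        # a 0-column (or 0-row) matrix has rank 0 by convention
        if entries.ndim == 2 and (entries.shape[0] == 0 or entries.shape[1] == 0):
            return 0
        raise DimensionError("cannot take the rank of an empty matrix")
    best = 0
    for t in range(trials):
        rng = np.random.default_rng((abs(int(seed)), t))
        magnitudes = rng.uniform(0.5, 1.5, size=entries.shape)
        best = max(best, int(np.linalg.matrix_rank(entries * magnitudes)))
    return best


def generic_rank(entries, trials: int = DEFAULT_TRIALS, seed: int = 0) -> int:
    """Structural rank of a sign pattern via random continuous realizations.

    Deterministic given ``seed``; exact with probability one because rank
    deficiency of a generic realization is a measure-zero event.
    """
    entries = np.asarray(entries)
    if entries.ndim != 2 or entries.size == 0:
        raise DimensionError(f"expected a nonempty 2-D sign matrix, got shape {entries.shape}")
    if trials < 1:
        raise DimensionError("trials must be >= 1")
    return _generic_rank_raw(entries, trials, seed)


# ---------------------------------------------------------------------------
# compliance report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplianceReport:
    """Per-criterion identifiability diagnostics for a connectivity pattern."""

    criterion1_ok: bool
    full_rank: int
    criterion2_ok: dict          # tf_id -> bool
    reduced_ranks: dict          # tf_id -> generic rank of its test submatrix
    criterion3_ok: bool          # n_conditions >= p (original-algorithm sufficiency)
    limited_data_ok: bool        # in-degree <= n for all genes AND regulon >= 2 for all TFs
    in_degrees: dict             # gene_id -> in-degree
    regulon_sizes: dict          # tf_id -> regulon size
    n_conditions: int
    offending_tfs: tuple
    offending_genes: tuple

    @property
    def compliant(self) -> bool:
        """Overall decision: criteria 1 and 2 plus the limited-data conditions.

        Criterion 3 is reported but not required: with in-degree <= n every
        per-gene regression stays determined, which is the regime that makes
        few-condition datasets analysable at all.
        """
        return self.criterion1_ok and all(self.criterion2_ok.values()) and self.limited_data_ok

    def to_dict(self) -> dict:
        return {
            "compliant": self.compliant,
            "criterion1_ok": self.criterion1_ok,
            "full_rank": self.full_rank,
            "criterion2_ok": dict(self.criterion2_ok),
            "reduced_ranks": dict(self.reduced_ranks),
            "criterion3_ok": self.criterion3_ok,
            "limited_data_ok": self.limited_data_ok,
            "n_conditions": self.n_conditions,
            "offending_tfs": list(self.offending_tfs),
            "offending_genes": list(self.offending_genes),
        }

    def to_text(self) -> str:
        lines = [
            f"compliant\t{self.compliant}",
            f"criterion1_full_column_rank\t{self.criterion1_ok}\trank={self.full_rank}",
            f"criterion3_conditions_ge_tfs\t{self.criterion3_ok}\tn={self.n_conditions}",
            f"limited_data_ok\t{self.limited_data_ok}",
        ]
        for tf, ok in self.criterion2_ok.items():
            lines.append(f"criterion2[{tf}]\t{ok}\trank={self.reduced_ranks[tf]}")
        if self.offending_tfs:
            lines.append("offending_tfs\t" + ",".join(self.offending_tfs))
        if self.offending_genes:
            lines.append("offending_genes\t" + ",".join(self.offending_genes))
        return "\n".join(lines) + "\n"


def _criteria_raw(entries: np.ndarray, n_conditions: int, seed: int, trials: int):
    """Criterion bookkeeping on a raw sign matrix; returns plain arrays."""
    m, p = entries.shape
    support = entries != 0
    full_rank = _generic_rank_raw(entries, trials, seed)
    c1 = full_rank == p
    c2 = np.zeros(p, dtype=bool)
    reduced = np.zeros(p, dtype=int)
    for l in range(p):
        rows = ~support[:, l]
        cols = np.arange(p) != l
        sub = entries[np.ix_(rows, cols)]
        r = _generic_rank_raw(sub, trials, seed) if sub.size else 0
        reduced[l] = r
        c2[l] = r == p - 1
    in_deg = support.sum(axis=1)
    reg = support.sum(axis=0)
    return full_rank, c1, c2, reduced, in_deg, reg


def check_compliance(pattern: ConnectivityPattern, n_conditions: int,
                     seed: int = 0, trials: int = DEFAULT_TRIALS) -> ComplianceReport:
    """Diagnose structural identifiability of ``pattern`` for ``n_conditions``.

    Always returns a report; inspect :attr:`ComplianceReport.compliant` for
    the overall decision.
    """
    full_rank, c1, c2, reduced, in_deg, reg = _criteria_raw(
        pattern.entries, n_conditions, seed, trials)
    offending_tfs = tuple(sorted(
        {tf for tf, ok in zip(pattern.tf_ids, c2) if not ok}
        | {tf for tf, r in zip(pattern.tf_ids, reg) if r < 2}))
    offending_genes = tuple(sorted(
        g for g, d in zip(pattern.gene_ids, in_deg) if d > n_conditions))
    limited_ok = bool((in_deg <= n_conditions).all() and (reg >= 2).all())
    return ComplianceReport(
        criterion1_ok=bool(c1),
        full_rank=int(full_rank),
        criterion2_ok={tf: bool(ok) for tf, ok in zip(pattern.tf_ids, c2)},
        reduced_ranks={tf: int(r) for tf, r in zip(pattern.tf_ids, reduced)},
        criterion3_ok=bool(n_conditions >= pattern.p),
        limited_data_ok=limited_ok,
        in_degrees={g: int(d) for g, d in zip(pattern.gene_ids, in_deg)},
        regulon_sizes={tf: int(r) for tf, r in zip(pattern.tf_ids, reg)},
        n_conditions=int(n_conditions),
        offending_tfs=offending_tfs,
        offending_genes=offending_genes,
    )


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PruneAction:
    kind: str     # "tf-removed" | "gene-removed"
    label: str
    reason: str   # regulon-too-small | tf-encoding-gene | rank-deficiency
                  # | in-degree-exceeds-conditions | orphaned-gene


@dataclass(frozen=True)
class PruneTrace:
    """Ordered record of removals; replaying it reproduces the pruned pattern."""

    actions: tuple
    initial_shape: tuple  # (m, p)
    final_shape: tuple

    def replay(self, pattern: ConnectivityPattern) -> ConnectivityPattern:
        genes = list(pattern.gene_ids)
        tfs = list(pattern.tf_ids)
        for a in self.actions:
            (genes if a.kind == "gene-removed" else tfs).remove(a.label)
        return pattern.restrict(genes=genes, tfs=tfs)

    def to_text(self) -> str:
        lines = [f"{a.kind}\t{a.label}\t{a.reason}" for a in self.actions]
        lines.append(f"final\t{self.final_shape[0]} genes\t{self.final_shape[1]} TFs")
        return "\n".join(lines) + "\n"


def _redundant_columns(entries: np.ndarray, trials: int, seed: int) -> list:
    """Column indices whose removal does not lower the generic rank."""
    rank = _generic_rank_raw(entries, trials, seed)
    out = []
    for j in range(entries.shape[1]):
        sub = np.delete(entries, j, axis=1)
        if sub.size == 0 or _generic_rank_raw(sub, trials, seed) == rank:
            out.append(j)
    return out


def prune_to_compliance(pattern: ConnectivityPattern, n_conditions: int,
                        tf_encoding_genes: Optional[Mapping[str, str]] = None,
                        seed: int = 0, trials: int = DEFAULT_TRIALS):
    """Greedily prune ``pattern`` to an NCA-compliant subnetwork.

    ``tf_encoding_genes`` maps a TF id to the label its encoding gene carries
    in the gene list (e.g. a TF present both as regulator and as a target of
    other TFs); such genes are removed first because the log-linear model
    cannot represent a regulator's own transcript as a target.

    Returns ``(pruned_pattern, PruneTrace)``; raises
    :class:`InfeasiblePruneError` (carrying the partial trace) when the
    network empties or nothing removable remains before compliance.
    """
    tf_encoding_genes = dict(tf_encoding_genes or {})
    genes = list(pattern.gene_ids)
    tfs = list(pattern.tf_ids)
    E = np.array(pattern.entries, dtype=np.int8)
    actions = []

    def fail(msg):
        trace = PruneTrace(tuple(actions), (pattern.m, pattern.p), (len(genes), len(tfs)))
        raise InfeasiblePruneError(msg, trace)

    def drop_genes(labels, reason):
        nonlocal E
        for g in sorted(labels):
            i = genes.index(g)
            genes.pop(i)
            E = np.delete(E, i, axis=0)
            actions.append(PruneAction("gene-removed", g, reason))

    # (1) genes encoding a retained TF
    encode = {tf_encoding_genes[t] for t in tfs if tf_encoding_genes.get(t) in genes}
    drop_genes(encode, "tf-encoding-gene")
    # (2) genes whose in-degree exceeds the number of conditions
    over = [g for g, d in zip(genes, (E != 0).sum(axis=1)) if d > n_conditions]
    drop_genes(over, "in-degree-exceeds-conditions")

    # (3) greedy TF removal until compliant
    while True:
        if not genes or not tfs:
            fail("pattern pruned to empty before reaching compliance")
        full_rank, c1, c2, reduced, in_deg, reg = _criteria_raw(E, n_conditions, seed, trials)
        limited_ok = (in_deg <= n_conditions).all() and (reg >= 2).all()
        if c1 and c2.all() and limited_ok:
            break
        # candidates: TFs with too-small regulons, or implicated in a rank deficiency
        small = {tfs[j] for j in range(len(tfs)) if reg[j] < 2}
        implicated = set()
        if not c1:
            implicated |= {tfs[j] for j in _redundant_columns(E, trials, seed)}
        for l in np.flatnonzero(~c2):
            implicated.add(tfs[l])
            rows = E[:, l] == 0
            sub = E[np.ix_(np.flatnonzero(rows), [j for j in range(len(tfs)) if j != l])]
            others = [tfs[j] for j in range(len(tfs)) if j != l]
            for k in _redundant_columns(sub, trials, seed):
                implicated.add(others[k])
        candidates = small | implicated
        if not candidates:
            fail("non-compliant but no removable TF identified")
        victim = min(candidates, key=lambda t: (int(reg[tfs.index(t)]), t))
        reason = "regulon-too-small" if victim in small else "rank-deficiency"
        j = tfs.index(victim)
        tfs.pop(j)
        E = np.delete(E, j, axis=1)
        actions.append(PruneAction("tf-removed", victim, reason))
        if not tfs:
            fail("all TFs removed before reaching compliance")
        orphans = [g for g, d in zip(genes, (E != 0).sum(axis=1)) if d == 0]
        drop_genes(orphans, "orphaned-gene")

    pruned = pattern.restrict(genes=genes, tfs=tfs)
    trace = PruneTrace(tuple(actions), (pattern.m, pattern.p), (pruned.m, pruned.p))
    return pruned, trace
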