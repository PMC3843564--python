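# Methods

## Model and assumptions

`ncakit` fits the log-linear regulation model

    log10 G = CS · log10 TFA,        G ∈ R^{m×n}, CS ∈ R^{m×p}, TFA ∈ R^{p×n}

in which a gene's log expression ratio (versus a control condition) is the
sum over its documented regulators of connectivity strength × log activity.
The model assumes: (i) regulation is multiplicative on the ratio scale and
additive in log space; (ii) connectivity strengths are shared across all
conditions, while activities vary by condition; (iii) the documented zero
pattern is correct — absent edges are truly absent (missing true edges bias
CS of the documented ones); (iv) no feedback: a TF included as a regulator
cannot also appear as a target gene, which is why pruning removes
TF-encoding genes first; (v) expression ratios are strictly positive and
already referenced to the control, so fitted log TFA reads directly as log
fold activity versus control. The log base is 10 throughout and is not
configurable.

## Structural identifiability and its limited-data surrogate

The decomposition is unique up to one scale (and sign) per TF iff the
pattern satisfies the compliance criteria:

1. the pattern has generic column rank p;
2. for every TF ℓ, the submatrix over the genes *not* regulated by ℓ and
   the other p−1 columns has generic rank p−1 (equivalently, no TF's
   regulon is structurally redundant given the rest — a regulon nested
   inside another's always fails);
3. the original algorithm's data-dimension condition n ≥ p.

Generic rank is computed numerically: each nonzero entry is replaced by an
independent uniform draw on ±[0.5, 1.5] and the numerical rank taken; the
maximum over 5 trials is exact with probability one at these matrix sizes,
and the test suite pins it against an exact symbolic-rank oracle on small
instances (exhaustively for the smallest shapes).

Typical curated studies violate criterion 3 (here: 7 TFs but only 4
conditions). The package therefore treats criterion 3 as reported-only, and
requires instead the conditions under which the alternating solver's
sub-problems remain determined: every gene's in-degree ≤ n (its private
regression has at least as many equations as unknowns) and every TF
regulates ≥ 2 genes. This surrogate is a design decision of this package —
the precise identifiability conditions of the limited-data variant of the
algorithm are not restated in the source literature — and it is exactly the
regime in which every least-squares half-step below is well-posed.

## Pruning

`prune_to_compliance` enforces, in order: (1) removal of genes that encode
a retained TF; (2) removal of genes with in-degree > n; (3) repeated
removal of the TF with the smallest regulon among those with < 2 targets or
implicated in a rank deficiency, dropping genes orphaned by each removal,
until the pattern is compliant. "Implicated" means the TF's own criterion-2
test fails, or its column is redundant (deleting it does not lower the
generic rank of the failing submatrix). Ties are broken lexicographically
by label, making traces deterministic; every removal is recorded with its
reason and the trace replays to exactly the final pattern. TFs are
preferred over genes for removal (beyond the two gene-specific rules)
because a wrong TF column corrupts all of its targets' regressions, whereas
genes are the data. The greedy trace-documented heuristic makes no claim of
maximality; finding the largest compliant subnetwork is not attempted.

## Solver

The fit minimizes ‖CS·logTFA − logG‖²_F by two-step least squares:

* CS-step: rows decouple; each gene solves an OLS over its k_i regulators
  (k_i ≤ n equations guaranteed by compliance). Genes are grouped by
  in-degree and solved as batched k×k normal systems.
* TFA-step: columns decouple; all conditions solve jointly via one
  least-squares solve against the m×p CS.

Each half-step is an exact minimizer given the other block, so the
objective is non-increasing at every half-step; the per-half-step objective
trace is stored on the result and asserted in tests. Iteration stops when
the relative objective decrease falls below `tol` (default 1e−9) or at
`max_iter` (default 1000). Initialization draws log TFA uniformly from
[−1, 1] — small-magnitude starts keep the first CS-step well-scaled for
log10-fold data — and CS is solved first. Because the problem is biconvex
but not convex, the solver runs `n_restarts` (default 10) seeded restarts
and returns the best final objective; restart r of a call seeded s uses the
independent stream (s, r), and replicate r of a multi-replicate fit is
seeded s + r. Run-to-run variability is treated as a first-class output
(restart index, trace and per-replicate dispersion are all surfaced), not
hidden. No regularization is applied: the estimator is plain two-step least
squares.

Singular CS-step systems (collinear regulator activities) raise an error
naming the gene rather than silently pseudo-inverting.

## Gauge, signs, aggregation

The raw factors are defined only up to per-TF reciprocal scaling.
`normalize_gauge` fixes each CS column to root-mean-square 1 over its
nonzero entries (activity row scaled reciprocally; the reconstruction is
unchanged to 1e−10). This convention is declared, not inherited: it makes
the customary |CS| > 1 "strong interaction" threshold mean "above the
column's typical magnitude". Absolute CS values should still be read as
relative, not physical, parameters.

`correct_signs` resolves the residual per-TF sign ambiguity by majority
vote over anchor edges — documented edges whose direction is
experimentally established. Documented-but-undirected edges (encoded +1 at
curation) never vote. A TF with no anchors or an exact tie is left
unflipped and flagged. Majority voting over all anchors, rather than one
designated witness pair, is the deterministic realization of "compare
against well-established pairs".

`aggregate` pools the best-of-restarts fit from each replicate:
element-wise mean and sample SD (ddof 1; a single fit reports SD 0), and a
per-edge classification — strong activation/repression when |mean CS| > 1
and the coefficient of variation |sd/mean| < `cv_max` (default 0.5; the
"low variability" criterion has no published threshold, so this is a
declared default), weak when 0 < |mean| ≤ 1, undetermined when large but
unstable, none off-pattern.

## Evaluation

* `reconstruction_r2` pools all gene×condition pairs into one scatter and
  reports R² = 1 − SS_res/SS_tot about the grand mean of the measured
  values; replicate sets are averaged per cell before comparison (pooling
  after averaging is a declared choice and is visible in the exported
  scatter file). The statistic is invariant under a common affine
  transform of both matrices.
* `tfa_mrna_parity` min-max normalizes ((x − min)/(max − min)) each TF's
  activity profile and the log10 expression profile of its encoding gene,
  and reports their Pearson correlation. Constant profiles return 0.5
  everywhere with a degeneracy flag (correlation NaN) so flat regulators
  still render. A composite regulator "A/B" is compared against each
  constituent separately.
* `pairwise_condition_test` applies a two-sided Welch t test per TF to
  every unordered condition pair over the replicate activities, flagged at
  strict p < α (default 0.05) with no multiplicity correction — matching
  common practice for this analysis; both choices are printed in the
  report. Two zero-variance samples compare by their means alone.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
the scale of the motivating floral study: sparse signed bipartite patterns
(defaults: 55 genes, 7 TFs, regulons of 2–12, 30% repression edges,
in-degree capped at n), activities i.i.d. Normal(0, `tfa_scale`²) in log10
units with `tfa_scale` = 0.5 (the literature gives no effect-size scale for
activity fold changes; this is a free default, chosen once), and replicate
ratios 10^(CS·logTFA + ε) with ε ~ Normal(0, σ²), σ = 0.05 log10 units, 3
replicates — multiplicative log-normal noise, the standard error model for
ratio microarray data. True |CS| magnitudes are bounded below (0.2 plus a
unit-mean Gamma draw, then gauge-normalized) so no edge is unidentifiably
weak by construction. Patterns are rejection-sampled until compliant.

What the generator does **not** emulate — probe-level artifacts, batch
effects, missing values, feedback loops, condition-dependent CS — bounds
what passing tests show: they demonstrate correct and well-conditioned
recovery under the model's own assumptions, not robustness to real
microarray pathology.

`floral_fixture` reconstructs the small floral-development network
recoverable verbatim from published running text (27 genes, 7 regulators,
including AGL15's four documented-but-undirected targets and the
HY5-activated/AP2-repressed pair HLH1 and RD20). It is intentionally not a
reconstruction of the study's full curated matrix; edges whose direction
the text does not state are encoded as documented activations. Because the
text names only two AP2 targets, both shared with HY5, AP2's regulon is
nested inside HY5's in this fixture and criterion 2 removes AP2 during
pruning — a structural property of the partial fixture, not of the full
published network.

## Numerical choices and degenerate inputs

Problem sizes in the test suite and acceptance script (50–55 genes, 7 TFs,
4 conditions, 50-seed recovery studies; exhaustive oracle enumeration only
at the smallest shapes with seeded sampling above) are chosen so the whole
suite runs in minutes on one CPU while still exercising the study-scale
regime. Other fixed choices: generic-rank trials 5; convergence by
relative objective change; lexicographic tie-breaks everywhere; strict
inequality at the α cutoff; ratio 1.0 ↔ log 0.0 exactly. Genes with
missing values are dropped at alignment with a warning (the model has no
missing-data mechanism); nonpositive ratios are errors, not warnings.

## Known limitations

* Greedy pruning can remove more than a minimal set; the trace documents
  what happened but no optimality is claimed.
* CS recovery degrades for TFs whose true activity spread is small
  relative to the noise (the signal the CS-step regresses on); with σ =
  0.05 and activity scale 0.5 this occasionally drops a column's recovery
  correlation below 0.95.
* Uncertainty is empirical (restarts × replicates); no analytic confidence
  intervals.
* The per-TF sign is undefined for TFs whose documented edges are all
  undirected; such TFs are flagged and their reported sign is arbitrary.
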