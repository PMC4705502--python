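# Methods

`danp-select` implements three linked pieces of multi-criteria decision
machinery — DEMATEL, ANP and their hybrid (DANP) — plus a comparison harness
for rank stability and elicitation effort. This note records the models, the
numerical choices, and what the synthetic tests do and do not demonstrate.

## The decision model

A decision network consists of a goal, one *strategy* cluster, one or more
*criterion* clusters whose elements are the sub-criteria, and a list of
project alternatives. The reference structure — a six-sigma project-selection
exercise in a medical centre — has 3 strategies, 15 sub-criteria in four
clusters (Benefit 5, Opportunity 4, Cost 3, Risk 3) and 6 candidate projects,
judged by a panel of 6 professionals. Dependency *blocks* declare which
cluster's elements receive weight in which other cluster's supermatrix
columns; the reference model declares within-cluster (self) blocks and
sub-criterion → alternative blocks.

## DEMATEL

Pairwise influence scores `a_ij ∈ {0..4}` form the direct-relation matrix
`A` (zero diagonal). The chain is:

- `k = min(1/max_i Σ_j |a_ij|, 1/max_j Σ_i |a_ij|)`, `M = kA`. The two-term
  minimum is used exactly (some variants use row maxima only).
- `S = M(I − M)^{-1}`, the closed form of `Σ M^t`; computed by a linear
  solve, with a warning when `cond(I − M) > 1e12` and a hard error when the
  spectral radius of `M` is ≥ 1 (the series would diverge).
- `D` = row sums, `R` = column sums of `S`; prominence `D + R`, relation
  `D − R`. `D − R > 0` ⇒ *dispatcher* (net cause, prioritized), `< 0` ⇒
  *receiver*. `|D − R| ≤ 1e-9` is classified *neutral* — group-aggregated
  matrices do produce exact zeros (the reference results contain one), so
  the two-way split is not exhaustive.
- The inner-dependence matrix column-normalizes `S` (each column sums to 1);
  it is the within-cluster block of the hybrid supermatrix.

`Σ(D) = Σ(R)` and `Σ(D − R) = 0` hold identically; the suite asserts them on
every computed output and on the published reference values.

## ANP

Comparison matrices on the Saaty 1–9 scale are validated for positivity,
unit diagonal, reciprocity (`a_ji = 1/a_ij`, tolerance 1e-9) and scale range
`[1/9, 9]`. Priorities are the principal eigenvector, computed by power
iteration from the uniform vector (sup-norm tolerance 1e-12, cap 10,000
iterations — unreachable for positive matrices, guarded anyway); `λ_max` is
the Rayleigh quotient at convergence. A general eigensolver is deliberately
not used: power iteration is deterministic, dependency-light, and for 3×3
reciprocal matrices it is cross-checked against the row-geometric-mean
closed form to 1e-12.

Consistency: `CI = (λ_max − n)/(n − 1)`, `CR = CI/RI(n)` with the random
index tabulated for `n = 2..10` (0, 0.58, 0.9, 1.12, 1.24, 1.32, 1.41, 1.45,
1.51); `CR ≤ 0.1` is acceptable. Orders above 10 are rejected rather than
extrapolated. `n = 2` with `CI > 0` is impossible for a true reciprocal
matrix and raises (it flags an upstream bug, not a judgment problem).

### Supermatrix

Nodes are all cluster elements followed by the alternatives. Each declared
block contributes a priority vector per target column; undeclared blocks are
zero. Alternatives are absorbing sinks (identity block): a plain hierarchy's
limit then reproduces the classical weighted-sum composition exactly, which
is the standard way to embed a hierarchy in the network formalism. Blocks
are scaled per target column by a cluster-weight matrix (equal split over
the declared source clusters by default) so every column sums to 1.

The limit is computed by repeated squaring until successive powers differ by
< 1e-10 in max-norm (up to 2^60). If the squared sequence is stationary but
one further multiplication moves it — a period-2 cycle, as in a two-element
swap matrix — the Cesàro average of the two alternating limits is returned
and flagged.

### Weight assembly

Local weights (LW) per cluster come from the within-cluster eigenvectors;
relative weights (RW) per criterion cluster come from the network
declaration (the reference model fixes all four at 0.25); global weights
compose as `GW = LW × RW`. Alternative scores compose the limit
supermatrix's absorption columns with the sub-criterion GWs. Two reporting
conventions are supported: `unit` (every cluster block sums to 1 — the
default for new analyses) and `paper` (criterion LW blocks and the
alternative block each sum to 0.5, the convention observed in the published
tables; exactly the unit values halved). Displayed values round half-up to
5 decimals, matching the published precision.

## The hybrid (DANP) coupling

The published description never writes the coupling equation, so the rule
follows the standard DANP literature and is isolated in one function
(`dematel_coupling`) so alternates can be swapped: each cluster's
inner-dependence matrix replaces that cluster's identity self-block in the
supermatrix. Feedback among a cluster's sub-criteria then redistributes
column weight before absorption, which is the entire numerical difference
between `run_anp` and `run_danp`; with identity inner blocks the hybrid
reproduces plain ANP bit-for-bit (asserted in the suite).

Influence is elicited within clusters only, so there is no inter-cluster
DEMATEL signal; the optional `cluster_weighting="dematel"` mode derives RW
as each criterion cluster's share of total-relation mass — the only
cluster-level reading the data supports — while the default keeps the
declared fixed RW, which is how the reference weights behave.

Matrices with `CR > 0.1` warn and the run continues (consistency is reported
post hoc); `strict=True` aborts listing the offending contexts.

## Robustness and agility harness

*Adequacy to change*: cloning an alternative appends a row/column copying
the clone target's comparisons with a mutual rating of 1 (reciprocity is
preserved by construction); cloning a sub-criterion duplicates its
row/column in the cluster's comparison and influence matrices and copies its
alternative-comparison matrix. Stability over the original items is reported
as a preservation flag, Kendall's τ and per-item displacement.

*Agility*: a judgment is an ordered off-diagonal entry — `n(n−1)` per
elicited matrix, counting `a_ij` and `a_ji` separately. This is the only
convention that simultaneously reproduces the reference totals of 500
(ANP: 6 strategy + 44 within-cluster + 450 alternative comparisons) and 550
(hybrid: + 50 influence entries), the +12 per sub-criterion for an added
alternative, and the +30/+36 for a sub-criterion added to a 3-element
cluster. Alternatives are compared per sub-criterion only (15 matrices) and
criterion-cluster weights are fixed, not elicited — also required to reach
exactly 500. The published incremental accounting excludes the enlarged
within-cluster comparison matrix under plain ANP (hence 30, not 36); both
that convention and the internally consistent one
(`include_within_cluster=True`, under which the increment equals the
before/after difference of totals) are implemented, neither presented as
correct.

## Synthetic data

The generator draws, per comparison context, a positive priority vector
whose consecutive sorted entries differ by a ratio in [1.3, 1.9], and per
cluster an integer 0–4 influence matrix in which every element both exerts
and receives some influence (a zero column would leave inner dependence
undefined). Participants perturb the implied consistent matrices:
multiplicative log-normal noise (σ = 0.1 by default) on the upper-triangle
ratios, snapped to the nearest Saaty value in log space (symmetric in `x`
vs `1/x`), reciprocals filled exactly; influence scores get additive
Gaussian noise (σ = 0.5), rounded and clipped to 0..4 with the diagonal
re-zeroed. Six participants by default; everything is deterministic under
the seed.

Alternative merit is *correlated across contexts*: one latent quality
ordering is drawn and each context perturbs it locally (adjacent swaps with
probability 0.3) before assigning its magnitudes. Ground truths whose
composed scores tie more closely than 0.02 (normalized) are rejected and
redrawn: snapping to the 17-value Saaty scale perturbs composed scores by
up to ≈ 0.01, so closer ties are unidentifiable by *any* elicitation on
that scale, and a recovery test over them would measure tie-breaking luck
rather than correctness.

What passing the synthetic tests shows: the pipelines invert the generative
model — priorities, consistency, composition and ranking are computed
correctly, and at zero noise the construction ranking is recovered on every
seed. What it does not show: anything about real panels, whose judgments are
not log-normal perturbations of a consistent matrix, whose inconsistency is
structured, and whose alternative merit may be less correlated across
criteria than the generator assumes. The aggregated-priority error bound
(0.05 L1 at σ = 0.1 with 6 participants) holds for unsnapped judgments;
with snapping, the quantization bias is shared by all participants and does
not average out, so only the mean error across contexts stays under that
bound.

## Problem sizes used in checks

The suite and the reproduction script run the full 24-node study structure
end to end; Monte-Carlo properties use 50 seeds (zero-noise ranking
recovery), 20 seeds (limit-matrix oracle) and 5–10 seeds for noisy-regime
statistics. The whole suite completes in a few seconds.

## Known limitations

- The published group-level weight tables cannot be reproduced numerically:
  the aggregated judgment matrices behind them were never published. They
  are checked as properties (balance identities, block-sum conventions,
  `GW = LW × RW`) and their printed values are embedded as anchors.
- The exact dependency declarations of the original study are not printed;
  the fixture's reading (within-cluster self blocks + sub-criterion →
  alternative blocks) is the most plausible one consistent with the
  published judgment totals.
- How the six participants' matrices were merged is unstated; geometric
  mean (comparisons) and arithmetic mean (influence) are the defaults, both
  selectable.
- No fuzzy extensions, no BOCR synthesis, no incomplete-matrix completion.
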