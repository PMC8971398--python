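# Methods

## The coarse-weight greedy fit

The model is a linear score s = Xβ with β ∈ {−1, 0, +1}^p, at most L
nonzero entries, fitted by greedy forward selection. The objective is one
of three *linearly invariant* metrics: the two-sided Welch
(unequal-variance) t-test p-value of case vs control scores (improves
downward from 1), the Mann–Whitney ROC AUC with ties counted ½ (improves
upward from 0.5), or the Pearson correlation with a continuous response
(improves upward from 0). Linear invariance — metric(c·s) = metric(s) for
any c > 0 — means only the direction of β matters, which is the modelling
assumption that makes unit weights sufficient.

Selection rule, per step: evaluate the metric of X(β ± e_k) for every
remaining zero entry k, scanning candidates in column order with +1 tried
before −1; keep the earliest candidate that no other candidate beats by
more than the tie tolerance, provided (after the first step) it strictly
improves the incumbent metric. The first step fixes the sign at +1 for
the binary metrics (the p-value and the whole-model mirror symmetry of
AUC make the leading sign a labelling convention; a reversed class coding
is handled by reporting flipped signs, not by refitting) and tries both
signs for correlation, where −1 may be needed to make the correlation
positive. Stopping: no improving candidate, L nonzero weights, or no
predictors left. The fit is deterministic; there is no randomness
anywhere in it.

The greedy search optimizes each step, not the final model: it can land
on a local optimum, and the test suite deliberately asserts per-step
optimality (against a brute-force rescan) rather than global optimality.

### Collinearity handling

A defining behaviour of the method is that exactly or nearly collinear
predictors never jointly enter a model: duplicating every column of X
must leave the solution unchanged, and of a predictor pair differing only
by a small perturbation at most one may be selected. Two mechanisms
deliver this:

1. **First-occurrence tie-break.** Identical candidates produce identical
   metrics; the earliest column wins the tie, so a copy of an unselected
   predictor is never preferred to the original.
2. **Duplicate exclusion.** A free column whose absolute correlation with
   any already-selected column is within `collinear_tol` (default 1e-4)
   of 1 is ineligible. This rule is needed because a pure per-step metric
   scan would happily select the *copy of an already-selected* column at
   a later step — the copy acts as an effective weight of 2 on a used
   predictor and can genuinely improve the metric — which would break the
   duplication invariance and re-admit exactly the collinear-pair
   pathology coarse weights are meant to avoid. The exclusion is inert on
   data in general position (random z-scored columns are never
   near-perfectly correlated) and makes the duplication invariance exact.

With `collinear_tol = 1e-4`, a perturbed twin with noise sd up to about
0.01 (on z-scored columns, correlation ≥ 0.9999) is treated as a
duplicate; larger perturbations make the twin a predictor in its own
right, which is the intended limiting behaviour.

### Numerical choices

- Tie tolerance 1e-12 (absolute) for metric comparisons; an exact tie is
  not an improvement. Note that for p-values far below 1e-12 the absolute
  tolerance is wide relative to the values; this only affects which of
  two astronomically small p-values counts as "better", and the
  conservative tie-counting in the permutation test points the resulting
  slack in the safe direction.
- Welch p-value degenerate cases: both groups constant with equal means →
  1.0 (no evidence); both constant with different means → the smallest
  positive double (perfect separation).
- A zero-variance score vector has correlation 0 in the candidate scan
  (as uninformative as the empty model); the scalar `pearson` raises
  instead, since a user calling it on degenerate input should hear about
  it.
- The empty model (β = 0) scores the metric's default value exactly; a
  first step whose best candidate exactly equals the default returns an
  empty model.

## Preprocessing

Predictors are z-scored with the sample (n−1) standard deviation;
exactly constant columns are rejected by name (detected by zero range as
well as zero sd, since the accumulated mean of a constant float column
need not be exact). A binary response must be coded 0/1 with at least two
members per class and is kept verbatim; a continuous response is
z-scored. Missing values are rejected, never imputed, and confounder
correction is assumed to have happened upstream. The on-disk dialect is
headered CSV with the response in the first column (overridable).

## Model assessment

**Permutation empirical p-value.** D refits on uniformly permuted copies
of Y (X untouched); E counts permuted fits whose final metric is at least
as good as the true fit's, ties counted (the conservative convention);
empirical p = (E+1)/(D+1) ∈ [1/(D+1), 1]. Under a true null the statistic
is uniform on its grid; the acceptance suite verifies this with a
Kolmogorov–Smirnov test over 200 independent null datasets at D = 99.

**Popularity.** Refits on `trials` random subject subsets
(`keep_fraction`, default 0.9), stratified per class for a binary
response (round(fraction × class size), minimum 2 per class), simple for
continuous; rows sampled without replacement within a trial, trials
independent. Counts of how often each predictor is selected are sorted
descending (stable at ties) and the largest drop between consecutive
sorted counts is reported as an advisory "cliff" rank — a suggestion for
the informative pool size, not a decision rule.

**Cross-validation.** Per trial the kept subset is drawn as above, *re-z-
scored*, fitted, and the kept subset's column means/sds are applied to
the holdout rows before scoring — the holdout never informs the scaling,
at the price of third-decimal differences versus reusing full-data
z-scores. The holdout metric is the Pearson correlation (continuous) or
AUC (binary). A column that is constant within a kept subset is zeroed
for that trial; a zero column cannot improve any metric and is therefore
never selected. A single-class holdout or degenerate score leaves that
trial's holdout metric missing (NaN), excluded from summaries and
counted. With `permute_target` the whole response is freshly permuted at
the start of every trial, yielding the matching null distribution of
holdout metrics.

**Limit sweep.** One permutation test per L in the requested range
(independent child seed streams from one root seed); the recommendation
is the smallest L whose empirical p-value is within 25% (relative,
user-overridable) of the minimum — "about the same, prefer smaller".

**Adjustment.** Simple OLS of Y on the score s = Xβ gives intercept b and
slope m in closed form, with the mean squared residual of b + m·s. An
affine map with m > 0 changes neither p-value, AUC nor correlation of the
score; it exists purely to put the coarse score on the response scale for
MSE comparison against real-weight methods.

All resampling draws from `numpy.random.default_rng` seeded by the
caller; identical inputs and seed give identical outputs.

## Synthetic data

The generator emulates the data regimes the method targets, and is the
basis of every test:

- **Binary cohorts**: standard-normal noise columns; each informative
  column's case-group mean is shifted by its effect size δ (in raw sd
  units) before the final z-scoring; default example shapes mirror
  realistic cohort dimensions (e.g. 40/32 controls/cases with 135
  predictors).
- **Continuous cohorts**: Y = Σ c_j X_j + σ·ε, z-scored. An allele-coding
  mode first discretizes columns to {−1, 0, +1} at the standard-normal
  tertile points before z-scoring, emulating SNP minor/heterozygous/major
  genotype coding (so each column takes at most three distinct values).
- **Copies**: exact duplicates (perturbation sd 0) or noisy twins with
  refreshed z-scores, for the collinearity properties.

What the generator does *not* emulate: linkage-disequilibrium structure
between SNPs, heavy-tailed assay noise, batch effects, or confounding.
Passing tests demonstrate the algorithmic properties (oracle equivalence,
invariances, calibration, recovery under Gaussian signal), not field
performance on real cohorts.

Default study conditions used by the acceptance script: oracle
equivalence on 100 random datasets (N = 40, p ≤ 8); collinearity checks
on 50 datasets; null calibration over 200 datasets (N = 30, p = 6,
D = 99); recovery on a 582-subject, 200-predictor allele-coded cohort
with four planted coefficients (0.30, 0.30, 0.25, 0.25, noise sd 1 —
population R ≈ 0.48 for the full signal, in the range typical of the
age-of-onset regime this emulates) with 200 popularity and 200 + 200
cross-validation trials.

## Known limitations

- Greedy: no global-optimality guarantee, by design.
- The absolute tie tolerance is coarse for p-values below ~1e-12 (see
  above).
- `collinear_tol` draws a hard line through the continuum between
  "perturbed twin" and "distinct predictor"; pairs with correlation just
  below the line are both eligible, and for them stability must come from
  the popularity analysis instead.
- Popularity counts and the cliff rank are advisory diagnostics; no
  automatic model selection is performed beyond the sweep recommendation.
- The 1.05^n ray-ratio bound is verified numerically (log-space, up to
  the requested dimension), not proven symbolically.
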