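# Methods

## The cross-lagged panel network model

`clpnet` treats a two-wave panel of p = 13 ordinal symptom items (the
GHQ-12, scored 0–3 with higher = poorer mental health, plus one
loneliness item scored 1–3) as observations of a directed network
process: each symptom at wave t+1 is modelled as a linear function of
*all* symptoms at wave t. Estimation is node-wise: for outcome j,

    min_beta  1/(2n) || y_j − X beta ||² + lambda_j || beta ||₁ ,

with an unpenalized intercept. The 13 coefficient vectors are stacked
into the weight matrix `W[j, i]` (path i → j). The diagonal is the
autoregressive path of each symptom; off-diagonal entries are
cross-lagged paths, each conditioned on the outcome's own autoregressive
effect and all other wave-t symptoms.

Assumptions worth stating explicitly:

- **Ordinal items are treated as continuous** in the regressions (no
  polychoric machinery); the discretization attenuates coefficients
  relative to an underlying continuous process (see *Bootstrap
  calibration* below).
- **Standardization**: predictors and outcomes are z-scored (population
  sd) on the estimation sample, so weights are comparable across items
  with different Likert ranges (0–3 vs 1–3) and invariant to affine
  rescaling of any raw item.
- The estimation sample for a wave pair is the set of subjects with
  complete (observed or imputed) responses at both waves.
- Within- and between-person variance remain entangled in such lagged
  regressions on panel data; the network describes between-subject
  prediction, not within-person dynamics.

## Penalty selection

Per node, 100 penalties descend log-spaced from that node's
`lambda_max = max_i |⟨x_i, y⟩|/n` (the smallest penalty with an all-zero
solution) to 0.001·lambda_max. Selection is by k-fold cross-validation
(default k = 10) minimizing prediction MSE. Two rules are supported:

- `"min"` (default): the grid point minimizing mean CV MSE;
- `"1se"`: the largest penalty within one standard error of that
  minimum (sparser networks).

The default follows the convention of the regularized-regression tooling
this workflow descends from, and matches the edge densities such
analyses report on real survey data (roughly three quarters of possible
edges nonzero). The trade-off is documented honestly: under a global
null (no true cross-lagged structure) the CV-minimum rule admits a small
number of spurious, tiny coefficients per node (~10% of entries in our
null simulations at n = 10 000), whereas the 1se rule is conservative
(0% spurious in the same simulations) at the cost of dropping true weak
paths and hub-recovery accuracy. Users who prioritize support recovery
over estimation accuracy should select `lambda_rule="1se"`.

**Fold assignment** hashes the subject id with the CV seed
(`crc32(f"{id}|{seed}") % k`), which makes the fit invariant to row
order and keeps a subject in the same fold when duplicated by a
bootstrap resample. Exact reproducibility therefore requires only the
data, the config and `cv_seed`.

## Solver

The LASSO path is computed by cyclic coordinate descent on the centered
Gram moments `G = X'X/n`, `c = X'y/n`, with warm starts along the
descending grid, soft-threshold updates, an incrementally maintained
gradient, and convergence declared when the largest coefficient update
in a sweep falls below `tol = 1e-7` (budget 10⁵ sweeps per grid point;
exceeding it raises). Working on the Gram matrix makes one path fit
O(p²) per sweep independent of n, and the whole 13-node × (k+1)-fit
cross-validation runs inside one compiled kernel; a full network fit
takes ~25 ms at n = 1000–4000, which is what makes full-procedure
bootstraps (penalty re-selected per resample) routine. Held-out fold MSE
is evaluated from the test fold's raw moments rather than per-row
predictions. `lambda_max` centers and divides in exactly the operation
order the solver uses for `c`, so a fit at exactly `lambda_max` is
identically zero, not zero up to rounding.

The solver is verified in the test suite against independent oracles:
normal-equation OLS at lambda = 0, the soft-threshold closed form on
orthonormal designs, a projected (split-coefficient) L-BFGS-B minimizer
on random problems, random-perturbation optimality checks, and
scikit-learn's `lasso_path` on a shared grid.

## Expected-influence centrality

One-step, signed, with the autoregressive diagonal excluded: out-EI of
node i is `Σ_{j≠i} W[j,i]`, in-EI of node j is `Σ_{i≠j} W[j,i]`. Signs
are preserved by definition (expected influence, not strength).
z-standardization for reporting uses the 13-node sample sd (n−1).
Cross-network centrality correlations are computed on raw values; since
z-scoring is a per-network affine map, Pearson r is identical either way
(this equivalence is itself a test).

A display threshold of 0.05 (strict `<`, the usual figure convention) is
available for reporting; it produces a copy. Centrality, bootstraps and
comparisons always use unthresholded weights.

## Bootstrap accuracy, difference tests, stability

- **Edge accuracy**: subjects are resampled with replacement; the
  *entire* estimation procedure (including per-node penalty selection)
  reruns per resample, since fixing the penalty understates variability.
  95% CIs are 2.5/97.5 empirical percentiles. Resamples that degenerate
  (a zero-variance item) are redrawn, at most 10 times, logged. Default
  n_boot = 1000; smaller values are accepted (with a warning below 1000)
  for desk-scale runs.
- **Difference tests**: two edges (or two nodes' centralities) differ at
  level alpha iff the (alpha/2, 1−alpha/2) percentile interval of the
  bootstrap distribution of their difference excludes 0. Tests are
  symmetric in their arguments, and self-comparisons are never
  significant. No multiple-testing correction is applied across the
  ~12 000 edge-pair tests — a deliberate convention of this literature
  and a caveat to keep in mind when reading the matrices.
- **Case-drop stability**: for drop proportions 0.1 … 0.7 (step 0.1),
  subjects are subsampled without replacement, the network re-estimated
  and centrality correlated with the full-sample centrality. The CS
  coefficient is the largest drop p such that at every p′ ≤ p at least
  95% of subsamples correlate ≥ 0.7; degenerate (zero-variance)
  subsample correlations count as failures.

Percentile bootstrap CIs of penalized estimates need not contain the
point estimate, and shrinkage biases them toward zero; the package
asserts only lower ≤ upper and finiteness.

**Calibration is evaluated against the estimand on the observed
scale.** Discretizing the latent process onto 3–4 Likert categories
attenuates the population regression coefficient (a latent path of 0.20
corresponds to ≈ 0.155 on the z-scored ordinal scale in the default
model). Empirical CI coverage is therefore measured against that
population (large-sample OLS) coefficient, not the latent weight;
residual undercoverage reflects LASSO shrinkage, which is why the test
brackets coverage in [88%, 99%] rather than pinning 95%.

## Imputation

Single-dataset predictive mean matching by chained equations (multiple
imputation with pooling is out of scope: there is no accepted pooling
rule for LASSO networks). Per incomplete variable: regress observed
values on all other item columns (every item at every wave) plus the
auxiliary covariates; draw regression parameters from their approximate
posterior (type-1 matching: observed cases predicted from the LS fit,
missing cases from the parameter draw); take the k = 5 observed cases
with closest predictions as donors; impute one donor's *observed* value
uniformly at random. Ten sweeps, variables visited in ascending
missingness order, missing cells initialized by random draws from the
observed values; a tiny ridge (1e-8) guards rank deficiency. Because
imputations are observed donor values, they are always in range and
never fractional. Auxiliary covariates default to sex, ethnicity *and*
age — age predicts dropout, so excluding it would weaken the MAR
adjustment; the configuration accepts the narrower sex + ethnicity set.

`complete_cases` implements the complete-case sensitivity filter.

## Descriptive statistics

Per item and wave: mean, sample sd (n−1), bias-adjusted skewness and
bias-adjusted *excess* kurtosis (normal = 0). Per wave, over subjects
with all 12 GHQ items: sum score (range 0–36, loneliness excluded),
caseness = sum > 11 (strict), Cronbach's alpha from the variance
formula, and McDonald's omega total `(Σλ)² / ((Σλ)² + Σψ)` from a
one-factor fit of the item covariance matrix by iterated principal-axis
extraction (max 500 iterations, tol 1e-6, loadings sign-fixed so
Σλ ≥ 0). Change across a wave pair: paired t on sum scores of subjects
scored at both waves (df = n−1; identically-zero differences give t = 0
rather than 0/0), and Hedges's g using the pooled sd of the two waves
with the small-sample correction J = 1 − 3/(4·df − 1). The g variant
(pooled occasion sd, not the sd of differences) and the bias-adjusted
moment conventions are package choices; published tables rarely state
theirs, so these are documented rather than asserted against any
external value.

## The synthetic generator

What it emulates: a sparse latent VAR(1) among 13 symptoms — wave-1
latents from a compound-symmetric correlation (0.35 among GHQ items,
0.25 with loneliness); wave t+1 = B·z(wave t) + Gaussian innovation,
with the wave-t latents z-scored before applying B so B lives on the
estimator's standardized scale; innovation sds set to keep latent
variances near 1. The default B has autoregressive diagonal 0.3 and ~20
cross-lagged paths (13 fixed backbone paths plus 7 seed-dependent
fillers, |weight| ∈ [0.10, 0.25]), with loneliness the designated
out-hub and feeling-depressed the in-hub; filler placement is
constrained (one extra outgoing path per source, one incoming per
destination, never out of the hub sources) so the hubs hold the largest
true expected influences for every seed. Thresholds are standard-normal
quantiles (cumulative 0.55/0.85/0.96 for 0–3 items, 0.65/0.88 for
loneliness), putting most mass in the low categories as in real symptom
data. Dropout is wave-level (whole interviews missing, as in panel
attrition) with logistic probability in sex, ethnicity and centered age
(~22% per wave at the defaults); item-level MCAR/MAR masking is
available separately for imputation tests.

What it does **not** emulate: household clustering, survey weights, mode
effects, item-level nonresponse patterns correlated with severity,
measurement non-invariance over waves, and any non-linear or
within-person dynamics. Passing recovery tests on this generator shows
the pipeline is statistically sound under its own model class — not that
real survey estimates are unbiased.

## Problem sizes and numerical choices in the test suite

Recovery experiments use n = 4000 (20 replicates), null sparsity
n = 10 000 (10 seeds), bootstrap calibration 50 replicates × 200
resamples at n = 1000 (the population coefficient from one n = 200 000
draw), stability 100 subsamples per drop level at n = 4000, imputation
robustness 10% missingness at n = 4000, and pipeline determinism
n = 500 with 100 resamples — sizes at which each check's Monte-Carlo
error is well inside its asserted margin. Edge-list correlations include
structural zeros of both networks by default (`nonzero_union_only`
restricts to the union of supports). Edge rankings break |weight| ties
lexicographically on (from, to) labels. Nonzero edge counts are exposed
with and without the autoregressive diagonal. All CSV/JSON outputs are
byte-reproducible given the same config and seeds; the run manifest
(config hash, seeds, versions, timings) is the one file excluded from
byte-level comparison, since it records wall-clock timings.

## Known limitations

- Between-person lagged associations only; no within-person
  decomposition, no contemporaneous network, no >2-wave joint model.
- CV-min penalties favor predictive accuracy over support recovery; see
  *Penalty selection* for the null-density consequence and the 1se
  alternative.
- Coverage statements concern the ordinal-scale estimand; latent-scale
  weights are attenuated by discretization.
- PMM with a single imputed dataset propagates no imputation
  uncertainty into the bootstrap CIs.
- Graph drawing/layout is out of scope; outputs are tables intended for
  external plotting.
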