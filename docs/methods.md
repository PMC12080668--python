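# Methods

## Predictive model

The predictive core is a two-stage regression applied identically to
connectivity edges and anatomical vertices.

**Stage 1 — screening.** For each feature x_j, the outcome is regressed on
[1, covariates, x_j] and the feature coefficient is tested with the exact
two-tailed t distribution (df = n − k − 2 with k covariate columns).
Internally this is computed by residualizing outcome and features against
[1, covariates] and correlating the residuals, which carries the same t
statistic as the coefficient in the full regression (Frisch–Waugh–Lovell);
it is vectorized over all features.  Features with p < `alpha_select`
(default 0.01) enter the positive or negative set by coefficient sign.
Zero-variance features are excluded with a logged count.  With
`selection="dp"` the candidate set instead comes from thresholding the
differential-power p-values, then is split by association sign.

**Stage 2 — strength regression.** Selected feature values are summed per
subject (one sum per sign set; `both` mode fits the two sums as separate
regressors, with an optional difference form).  The optional
correlation-weighted variant multiplies each value by its training-set
(partial) correlation with the outcome — the same correlation used for
selection, so weighting and selection stay consistent when covariates are
present.  Ordinary least squares relates the outcome to the strength(s).

**Covariate schemes.** `predictors` appends covariates to both stages'
designs.  `nuisance` includes them in stage 1, then in stage 2 estimates
outcome∼covariates and strength∼covariates on the training set,
residualizes both, fits the residual regression, and at prediction time
residualizes the test strengths and adds the estimated nuisance effects
back, so predictions are on the instrument scale.  In leave-one-out
cross-validation the single held-out subject is residualized with training
coefficients (its own are inestimable); in external validation the test set
is large enough that its own nuisance coefficients are estimated by
default (reducing covariate-shift risk), with the train-coefficient carry-over
available as an option.  Note the test-set estimate uses the observed test
outcomes; this is an evaluation protocol, not a deployment predictor, and
the API requires those outcomes explicitly.  Scanner enters as indicator
columns (first level dropped).

**Degenerate folds.** A fold whose selected set is empty gets strength 0
for all subjects; the zero column is dropped from the design (its
coefficient reported as exactly 0), the fold reduces to
intercept(+covariates), and the fold index is flagged in the report.
Failing an entire cross-validation for one empty fold would discard more
information than an intercept-only prediction.

**Metrics.** MAE, Pearson r, and the cross-validation R² (1 − SS_res/SS_tot
around the observed mean; unbounded below, not r²).  Confidence intervals
are percentile bootstrap over observed–predicted pairs (default 1000
resamples): the final prediction pairs are resampled, not the whole
cross-validation loop, matching the interpretation of the intervals as
uncertainty in the performance summary given the predictions.  Degenerate
resamples (e.g. constant observed values under an r or R² metric) are
redrawn with a logged count and an error if they exceed 10% of draws.
Pair-level resampling is the simpler of the two defensible readings and is
isolated behind one function should a refit-per-resample variant be wanted.
The motion pre-check is a two-tailed permutation test of the correlation
between mean framewise displacement and the outcome (default 10,000
permutations, add-one convention so p ≥ 1/(n_perm+1)).

## Fingerprinting and differential power

Similarity is the full N×N Pearson matrix between baseline and follow-up
feature vectors; identification takes the row (or column, for the reverse
direction) argmax with replacement.  Exact ties — measure-zero for real
data but constructible synthetically — break to the lowest index with a
logged warning, or uniformly at random under a seed.  The count of correct
identifications is tested against Binomial(N, 1/N); the tail is accumulated
from `binom.logpmf` in log space, and a log-scale variant is provided for
values below the smallest positive float (the plain value then floors at
that float rather than underflowing to zero).

Per-feature contributions standardize both vectors to population variance 1
and take c_i = x_i y_i / n, which sums to Pearson r exactly.  The chance
probability that a feature's within-subject product is matched by chance
compares, for subject s, the product x_s·y_s against the 2(N−1) cross
products x_s·y_t and y_s·x_t (t ≠ s; both directions enter symmetrically,
ties count against discriminability):

    p̂ = (#{cross ≥ within} + 1) / (2(N−1) + 1)

The add-one smoothing bounds p̂ in [1/(2N−1), 1] — strictly positive, so
log-combination is always defined.  The smoothing constant is isolated in
one function.  Differential power sums −2 ln p̂ over subjects and refers
the sum to χ²(2N).  Because 2N is even, the survival function has the exact
Erlang closed form exp(−x/2)·Σ_{j<N}(x/2)^j/j!, which is evaluated by
log-sum-exp; this keeps extreme DP p-values finite in log space where the
generic survival function would underflow.

**Calibration caveat.** The χ²(2N) reference is exact when the underlying
chance probabilities are uniform on (0,1).  The estimator p̂ is discrete
and add-one smoothed, so −2 ln p̂ is stochastically *smaller* than χ²(2)
(its null mean is ≈1.94 rather than 2 at N = 60), making DP p-values
conservative — never anticonservative.  The test suite checks exact
uniformity on the uniform-p̂ route and conservativeness on the estimator
route.  Practically this means DP selection at a nominal α admits slightly
fewer than α·F null features.

## Synthetic cohorts

The generator emulates the data layout of a two-dataset pediatric treatment
study: dataset A (default n = 54) for training/cross-validation, dataset B
(default n = 15) for external validation; 216 nodes → 23,220 edges; a
20,484-vertex mesh with 18,742 active cortical vertices (the trailing
vertices are constant across subjects, exercising the variance-based mask).

Per feature, session values decompose as group mean + subject-stable offset
+ independent session noise.  Defaults: edge subject-effect SD 0.10 with
session-noise SD 0.10 (identifiable but noisy, fingerprint accuracy high
yet imperfect at small feature counts); anatomical subject-effect SD 0.50
with session-noise SD 0.01 (near-deterministic repeats, ~100%
identification, mirroring the much higher test–retest stability of
morphometry).  These variance components are free parameters of the
emulation — no published stability coefficients exist for the motivating
data — and the extremes (zero session noise; zero subject effect) are what
the calibration tests pin down.

The outcome is y = intercept + β_strength·Σ(planted edges) + β_age·age +
β_sex·sex + β_baseline·baseline + N(0, σ), clipped to the 0–25 instrument
range.  Ages are uniform on [8, 17], sex Bernoulli(1/2), baseline severity
uniform on [9, 25] (the clinical cut-off floor), mean framewise
displacement log-normal around 0.12 mm.  Defaults (β_strength 0.5 over 10
planted edges, σ = 2) give a weak, realistically hard signal at n = 54.  A
config switch couples baseline severity to the planted brain signal; another
adds a scanner offset.  Time series from a latent-factor model are available
for exercising the correlation/GSR/partial path; edge values are otherwise
generated directly on the Fisher-z scale for exact statistical control.

What the generator does **not** emulate: spatial autocorrelation of edges
and vertices, network-structured signal topography, site/sequence
differences between the two datasets beyond an additive offset, outcome
floor effects from treatment response heterogeneity, and motion–outcome
coupling.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated variance model, not robustness to
those real-data properties.

## Simulation scales and numerical choices

- Null calibration runs 100 no-signal cohorts of n = 60 with 2,016 edges
  (64 nodes), intercept 12.5 so the clipped instrument range never censors
  the Gaussian outcome (censoring would distort the t-test calibration that
  the check is about).
- Planted-signal recovery uses n = 200, 120 edges (16 nodes), 5 planted
  edges at β_strength 3 and σ = 0.5: each planted edge then carries ~16% of
  outcome variance, giving >99% per-fold selection power, and the ~1
  expected false positive at α = 0.01 cannot dilute the strength sum below
  a leave-one-out r of 0.7.  With F candidate features, α·F false
  positives bound the achievable LOO r near √(k_true/(k_true+α·F)) times
  the true-model r — the reason the planted fixture uses a compact edge
  pool.
- Fingerprint chance-level checks average 200 replicates of N = 15.
- Correlations with |r| ≥ 1−1e−12 are clipped before atanh on the
  time-series path only; user-supplied matrices with non-finite entries are
  rejected (a data error, not a numerical one).  Symmetry tolerance 1e−10.
- Partial correlations use the exact inverse covariance when well
  conditioned and a Ledoit–Wolf shrinkage estimate when n_timepoints ≤
  n_nodes or the condition number exceeds 1e12.
- Vertex-mask variance threshold 1e−12; edge order is fixed row-major upper
  triangle (i < j), the identity that `unwrap`/`rewrap` round-trip.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; same seed → byte-identical serialized outputs.

## Known limitations

- OLS only in the second stage (no robust/regularized variants), matching
  the framework being studied.
- DP selection feeds CPM with a fixed DP result computed once on the
  two-session sample; it is not recomputed inside each LOO fold.
- The bootstrap does not refit the model per resample (see above); interval
  coverage is assessed by simulation for MAE in the test suite.
- GIFTI/CIFTI surface formats and BOLD preprocessing are out of scope; the
  feature layer reads plain tab-separated tables and documents the
  conversion hook.
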