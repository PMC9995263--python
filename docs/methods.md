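# Methods

## The estimand and the two estimators

A multivariate BWAS model maps a feature vector (here: many correlated
continuous features standing in for vectorized connectivity matrices) to a
predicted continuous phenotype. Its effect size is the Pearson correlation
`r` between predictions and observed outcomes. Two estimators of the
discovery-sample effect are distinguished everywhere:

- **in-sample**: `r` computed on the training samples themselves. For any
  flexible model this is inflated by overfitting — in the extreme, a
  weakly regularized ridge with `p ≥ n` interpolates the training outcomes
  and reports `r ≈ 1` on pure noise.
- **cross-validated (CV)**: `r` between pooled out-of-fold predictions and
  outcomes. Each prediction comes from a model that never saw that sample,
  so the estimate is unbiased up to a small pessimism (fold models train on
  `n(k−1)/k` samples rather than `n`).

Replication is evaluated by refitting one model on the entire discovery
subsample and applying it, frozen, to a disjoint replication subsample of
the same size. The CV ensemble is never used for replication: replication
is meant to validate the single model a study would publish.

## Synthetic-data generator

Features are zero-mean unit-variance Gaussians in equicorrelated blocks
(within-block correlation `block_rho`, blocks independent). One standard
normal weight is drawn per block and shared by the block's signal-carrying
features, so the predictive signal lies in the shared low-rank structure of
the features — mirroring connectivity data, where predictive information
concentrates in large-scale components rather than in idiosyncratic edge
noise. With `f = Xw` standardized by its closed-form population standard
deviation, the outcome is

    y = rho_true * f_std + sqrt(1 - rho_true^2) * eps,

so the population correlation between the optimal linear predictor and the
outcome is exactly `rho_true` and `rho_true^2` is the variance explained.
This closed form is the oracle for parameter-recovery and calibration
tests.

Defaults, chosen once as a desk-scale analogue of connectome-phenotype
studies: `n_samples = 1200`, `n_features = 200`, `n_signal = 100`,
`block_size = 10`, `block_rho = 0.9` (effective feature rank ≈ 20,
emulating features derived from a few dozen ICA nodes), `rho_true = 0.3`
(variance explained 9%, the upper range of strong connectivity-cognition
effects). A companion generator produces Gaussian node timeseries from a
sparse, diagonally dominant precision matrix together with the implied true
partial-correlation matrix, for testing the network-matrix pathway.

What the generator does *not* emulate: non-Gaussian and heteroscedastic
features, site and motion confounds, phenotype measurement unreliability,
and the long-tailed dependence structure of real connectomes. Tests passing
on this generator therefore demonstrate the statistical mechanics of the
framework (estimator bias, calibration, selection effects), not performance
claims about any real dataset.

## Prediction pipelines

Both pipelines standardize features with training-fold statistics.

- `pca_svr`: PCA retaining the smallest number of components reaching 95%
  explained variance, capped at `min(n_train − 1, 250)`; then linear-kernel
  support-vector regression (`C = 1`, `epsilon = 0.1`). The SVR convergence
  tolerance is 0.1 rather than the library default 1e-3: in noise-dominated
  fits the SMO solver otherwise spends seconds polishing KKT conditions
  that change the prediction-outcome correlation by less than 0.01. All
  SVR/PCA settings are recorded in the fitted model's metadata.
- `ridge`: ridge regression with shrinkage fixed at 1 (the conventional
  default for partial-correlation features); no tuning, deliberately — the
  framework studies fixed pipelines, and hyperparameter search would itself
  be a leakage risk.

With standardized features and shrinkage 1, ridge is nearly unregularized
at these problem sizes; at `n ≈ p` it sits close to the interpolation
threshold, which produces the textbook pathologies the benchmark is built
to expose (in-sample `r ≈ 1`, attenuated out-of-sample `r`, a dip in
replication performance near `n = p`).

`cross_validated_predictions` refits the entire pipeline inside every fold
of a seeded k-fold split (default `k = 10`, single repetition; repeated CV
averages out-of-fold predictions over reshuffled partitions). The CV effect
size is the single correlation over all pooled out-of-fold predictions, not
the mean of per-fold correlations — lower variance and standard practice.

Partial-correlation matrices are computed from the (optionally
ridge-regularized) precision matrix, `-Ω_ij/√(Ω_ii Ω_jj)`; the default
covariance regularization 0.1 × mean diagonal keeps the inversion stable
for short timeseries. Edge vectorization is the strict upper triangle in
row-major order.

## Inference

Parametric p-values use the exact t transform `t = r√((n−2)/(1−r²))` with
`n−2` degrees of freedom; confidence intervals use the Fisher z
approximation. Both are exact or near-exact when predictions are fixed
relative to the outcomes — in particular for replication effects, where the
frozen model is independent of the replication sample.

They are *not* valid for the pooled CV correlation: out-of-fold predictions
depend on the other folds' outcomes, prediction errors are correlated
within folds, and the null distribution of the CV `r` is overdispersed
relative to the t null (measured sd ≈ 0.14 at `n = 100` against the nominal
`1/√n = 0.10`, one-sided type-I rate ≈ 0.11–0.13 at nominal 0.05; neither
fold count nor repeated CV removes the effect). The benchmark therefore
calibrates the discovery test by permutation by default
(`cv_p_method = "permutation"`): for each grid sample size a
permuted-outcome null distribution of the CV `r` (200 draws) is computed
once and every replicate's p-value is its add-one rank in that null. The
parametric construction remains available (`cv_p_method = "parametric"`)
and is the default for standalone effect estimates, where the caveat is
documented rather than hidden.

A "positive result" is directional: a significant *positive* `r` (a
significantly negative prediction-outcome correlation is a failed model,
not a replication). The benchmark's significance tests are accordingly
one-sided at level α by default, which makes the discovery-positive rate
equal α under the null; two-sided testing combined with the `r > 0`
requirement (rate α/2 under a symmetric null) is available via
`sidedness`.

## Benchmark design

- Discovery and replication subsamples are drawn without replacement and
  are disjoint within a replicate; across replicates individuals recur
  (bootstrap over subsamples). Replicate seeds derive deterministically
  from `(seed, n, replicate_index)`, so results are independent of
  execution order and worker count, and extending the number of bootstrap
  replicates preserves the existing ones.
- Per-`n` metrics: mean inflation (`r_discovery − r_replication`) for both
  estimators; power = fraction of discovery-positive replicates; `P_rep` =
  fraction of discovery-positive replicates that are also
  replication-positive (NaN sentinel with subset size 0 when no replicate
  is discovery-positive — never a silent zero); conditional inflation under
  a configurable significance conditioning, default discovery-side (the
  standard publication-bias construction; replication-side and both-sides
  conditioning are available, since either convention appears in the
  literature). Intervals are 95% percentile bootstrap over replicates
  (1,000 resamples, seeded).
- `min_n` returns the first grid sample size whose metric reaches the
  threshold, with no interpolation, and the sentinel `">MAX"` when the grid
  never reaches it (the "arrow bar" convention of sample-size charts).
  Non-monotone profiles are logged and the first-crossing rule applied
  unchanged.
- Replicates with degenerate subsamples (constant outcome) are excluded
  and logged; a run aborts if more than 10% are invalid.

## Analytic power

Under the Fisher z transformation, `atanh(r)` is approximately normal with
mean `atanh(ρ)` and standard error `1/√(n−3)`, giving

    power(rho, n) = Phi(atanh(rho) * sqrt(n-3) - z_{1-alpha/2})

(two-sided; the vanishing opposite tail is included for completeness).
`required_n` starts from the inverted expression and then walks to the
exact minimal `n` by direct evaluation — the un-refined ceiling formula can
be off by one (e.g. it suggests 390 where the minimal `n` with power ≥ 0.8
is 391 at ρ = √0.02). A vectorized Monte-Carlo simulator provides an
independent check; closed form and simulation agree to within 0.02 for
`n ≥ 50`, `ρ ≤ 0.5`.

## Problem sizes and numerical choices

The test suite and the analysis scripts run the benchmark at
`n ∈ {50, 100, 200, 400}` with 100 bootstrap replicates (200 under the
null) on the 1,200 × 200 reference dataset, and the permuted-outcome
analysis at `n = 200` with 2,000 features and 100 permutations — sizes at
which every qualitative regime (underpowered, near-interpolation, well
powered) is represented while a full run stays in the minutes range on one
CPU. Dataset text round-trips are written with 17 significant digits
(lossless for doubles). Correlations on constant vectors raise an error
rather than returning 0; `|r| = 1` boundaries are flagged explicitly.

## Known limitations

- The exact pipeline configurations of published PCA+SVR analyses
  (component counts, SVR parameters) vary; numeric parity with any specific
  study is not claimed, only the method class.
- The Fisher-z "prospective replication" variants used by some power
  calculators differ slightly from the plain closed form used here; the
  `required_n` routine exposes the standard form only.
- Permutation calibration of the discovery test shares one null sample per
  grid `n` across replicates; replicate p-values are therefore weakly
  dependent through the null (marginally calibrated, measured type-I 0.03
  at nominal 0.05 with B = 200).
- `P_rep` estimates at small `n` condition on few discovery-positive
  replicates and are correspondingly noisy; the reported subset sizes
  should always be read alongside the values.
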