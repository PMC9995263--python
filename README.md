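# bwasrep

Replicability analysis for **multivariate brain-wide association studies
(BWAS)** — studies that train a predictive model over many brain features
(for example, vectorized connectivity matrices) to explain inter-individual
differences in a continuous phenotype.

The package is built around one distinction with large practical
consequences: the *effect-size estimation method* (in-sample versus
cross-validated) is not the same thing as the *sample* (discovery versus
replication). The in-sample prediction–outcome correlation of a flexible
model, computed on its own training data, is inflated by overfitting and is
not a valid effect-size estimate; the cross-validated correlation between
pooled out-of-fold predictions and outcomes within the discovery sample is
essentially unbiased. Once discovery effects are estimated with
cross-validation, moderately sized studies can be adequately powered and
replicable — the sample sizes required are governed by the true effect size,
not by the overfitting artefact.

## What it computes

For a model whose predictions `ŷ` are compared with outcomes `y` by the
Pearson correlation `r = corr(ŷ, y)`:

- **Discovery/replication bootstrap** (`bwasrep.bench`): at each sample size
  `n`, repeatedly draw *disjoint* discovery and replication subsamples,
  train on discovery, and record the in-sample `r`, the cross-validated `r`
  (out-of-fold), and the replication `r` of the frozen model. Derived
  per-`n` metrics: mean effect-size inflation `Δr = r_discovery −
  r_replication` for both estimators, in-sample power, out-of-sample
  replication probability `P_rep`, and inflation conditional on significance
  (the winner's curse / publication-bias construction), with percentile
  bootstrap intervals and first-crossing minimal-`n` lookup.
- **Prediction pipelines** (`bwasrep.models`): PCA + linear support-vector
  regression, and ridge regression with a fixed shrinkage parameter of 1 —
  both strictly leakage-free (all preprocessing refit inside every
  cross-validation fold) — plus partial-correlation network matrices and
  their edge vectorization.
- **Effect inference** (`bwasrep.inference`): `r` p-values via the exact
  t transform `t = r√((n−2)/(1−r²))`, critical values, Fisher-z confidence
  intervals `tanh(atanh r ± z/√(n−3))`, and permuted-outcome null
  distributions of either estimator.
- **Analytic power** (`bwasrep.power`): Fisher-z power
  `Φ(atanh(ρ)·√(n−3) − z_{1−α/2})` and minimality-checked required sample
  sizes, with a Monte-Carlo cross-check.
- **Synthetic data** (`bwasrep.synthetic`): a linear-Gaussian generator with
  block-correlated features whose population effect size `ρ_true` is exact
  by construction, so every estimator can be tested against a known truth.

## Worked example

```python
import bwasrep as b

ds = b.generate_dataset(b.GroundTruthConfig(rho_true=0.3, seed=5))
cfg = b.BenchmarkConfig(n_grid=(50, 100, 200, 400), n_bootstrap=100,
                        model=b.ModelSpec(family="ridge"), seed=42)
records = b.run_benchmark(ds, cfg)
table = b.aggregate(records, cfg)
```

The same experiment is scripted as `analysis/02_effect_size_inflation.py`,
which prints:

```
per-sample-size summary (rho_true = 0.3, ridge, B = 100):
metric  mean_inflation_insample  mean_inflation_cv  power  p_rep
n
50                        0.870             -0.084   0.10  0.100
100                       0.884              0.011   0.29  0.310
200                       0.870              0.025   0.37  0.297
400                       0.611             -0.015   0.60  0.867
```

Reading: the in-sample (non-CV) discovery estimate exceeds the replication
effect by 0.6–0.9 at every sample size — that is overfitting, not biology —
while the cross-validated estimate tracks replication to within a few
hundredths (slightly pessimistic at `n = 50`, where each fold model trains
on very few samples). Power and `P_rep` rise with `n`; `P_rep ≥ 0.8` is
first reached at `n = 400` on this grid.

The permuted-outcome analysis (`analysis/03_permutation_null.py`) makes the
estimator bias explicit — with outcomes shuffled so there is nothing to
find, in a 2,000-feature / 200-sample regime:

```
pca_svr  in-sample null r: mean +0.715 [+0.597, +0.797]
ridge    in-sample null r: mean +1.000 [+1.000, +1.000]
ridge    CV null r:        mean +0.014 [-0.167, +0.172]
```

And the analytic side (`analysis/05_analytic_power.py`): a true effect
explaining 1% of outcome variance (ρ = 0.1) needs `n = 783` for 80% power
at α = 0.05, and 2% needs `n = 391` — comfortably below a thousand
participants.

## Command line

```sh
bwasrep generate --rho-true 0.3 --out results/data
bwasrep bench --config configs/example.yaml --jobs 4
bwasrep nulls --config configs/example.yaml
bwasrep power --rho 0.1 --rho 0.2 --n 200 --n 800
bwasrep validate --config configs/example.yaml
```

Every run writes a self-describing output directory (records, tidy metrics,
minimal-`n` summary, config echo with seeds and library versions); numeric
outputs are bit-for-bit reproducible from the config and independent of
`--jobs`.

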