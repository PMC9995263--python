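# Full synthetic benchmark: one reviewable artifact describes the experiment.
data:
  synthetic:
    n_samples: 1200
    n_features: 200
    rho_true: 0.3
    n_signal: 100
    block_size: 10
    block_rho: 0.9
    seed: 5

benchmark:
  n_grid: [50, 100, 200, 400]
  n_bootstrap: 100
  alpha: 0.05
  k_folds: 10
  conditioning: discovery_significant
  sidedness: one_sided
  cv_p_method: permutation
  n_null_permutations: 200
  seed: 42
  model:
    family: ridge
    ridge_shrinkage: 1.0

permutation:
  estimators: [in_sample, cv]
  n_permutations: 100
  n_grid: [100, 200]

output_dir: results/experiment
min_n_threshold: 0.8
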