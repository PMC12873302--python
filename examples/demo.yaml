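# Small synthetic demo: AD-like alpha decoupling vs controls, desk scale.
cohort:
  group_sizes: {AD: 8, HC: 8}
  n_channels: 8
  epochs_per_subject: [10, 14]
  alpha_coupling: {AD: 0.42, HC: 0.5}
  delta_power_scale: {AD: 1.2}

pipeline:
  bands: [alpha, theta]
  metrics: [Cov, Corr, PLV]
  problem: [AD, HC]
  metric: log_euclidean
  n_folds: 5
  alpha: 1.0
  l1_ratio: 0.15
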