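scenario:
  n_subjects: 1500
  baseline: weibull
  rate: 0.1
  shape: 1.2
  covariates:
  - name: x1
    dist: normal
    mean: 0.0
    sd: 1.0
    prevalence: 0.5
  - name: x2
    dist: normal
    mean: 0.0
    sd: 1.0
    prevalence: 0.5
  - name: x3
    dist: binary
    mean: 0.0
    sd: 1.0
    prevalence: 0.4
  true_coefficients:
  - 0.5
  - -0.3
  - 0.7
  slope_multiplier: 0.8
  baseline_hazard_multiplier: 1.0
  case_mix_shrinkage: 1.0
  nonph_delta: 0.0
  nonph_index: 0
  admin_horizon: 7.0
  uniform_censoring: null
  seed: 42
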