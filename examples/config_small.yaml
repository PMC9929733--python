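cohort:
  n_admissions: 60
  seed: 7
  ar_coefficient: 0.7
  covariate_flags: true
learners:
  sample_size: 400
  n_folds: 5
  seed: 11
  rf_n_estimators: 30
  feature_sets: [model_A, model_B]
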