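# Minimal end-to-end configuration for `wardsense run-all`.
cohort:
  n_participants: 8
  stay_mean_days: 10
  stay_sd_days: 3
  stay_min_days: 8
  stay_max_days: 14
experiment:
  k_folds: 2
  max_epochs: 3
  scales: [BPRS, HAMA, MADRS, YMRS]
  tasks: [deterioration, score]
  run_importance: false
  run_tsne: false
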