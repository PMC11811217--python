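# Demo-scale end-to-end run: 40 simulated subjects, single-seeded.
output_dir: runs/demo
seed: 0
min_beats: 10

cohort:
  n_subjects: 40
  prevalence: 0.5
  segments_per_subject: [6, 6]
  segment_duration_s: [15.0, 15.0]
  sampling_rate_hz: 125.0
  heart_rate_bpm: [55.0, 90.0]
  causal_effect: 1.0
  confounder_effect: 1.2
  noise_sd: 0.02

screening:
  test: mannwhitney
  alpha: 0.05
  cap: 12
  fdr: false

score:
  kind: bic
  penalty: 1.0

fusion:
  runs: 10
  frac: 0.8
  threshold: 0.5

evaluation:
  folds: 10
  algorithms: [random_forest, logistic_regression, decision_tree, naive_bayes]
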