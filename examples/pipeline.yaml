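# Full pipeline configuration. Every block is optional; unknown keys are
# rejected. Values shown are the defaults unless noted.
seed: 1
out_dir: kinemetrix_out
log_level: INFO

smoothing:
  window: 5
  sigma: 0.5

segmentation:
  min_duration_s: 3.0
  max_duration_s: 8.0
  invalid_halo_s: 0.333
  flicker_window_s: 0.5
  flicker_min_crossings: 3
  smooth_before_masks: true

labels:
  threshold_mode: sample_median   # or "fixed"
  fixed_threshold: 32

spectral:
  nperseg: 128
  overlap_frac: 0.5
  window: hann
  detrend: constant

modeling:
  n_repeats: 16
  base_seed: 1
  inner_cv: grouped_kfold         # or "loso" for full nested LOSO
  inner_k: 5
  classifiers: [lda, lr, svm, rf, ab, knn, gnb]

simulate:
  n_subjects: 20
  recordings_per_subject: 1
  duration_s: 30.0
  fps: 30
  fraction_severe: 0.5
  theta_mild: 0.2
  theta_severe: 0.8
  noise_sd: 0.002
  seed: 1
  artifacts:
    n_dropout: 1
    n_flicker: 1
    n_crouch: 1
    n_both_raised: 1
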