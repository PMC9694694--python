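# Complete annotated pipeline configuration (production defaults).
# Load with: csarima --config this_file.yaml ...  or PipelineConfig.from_yaml().

sampling_minutes: 5        # CGM grid spacing
pp_window_samples: 48      # postprandial window: 4 h of 5-min samples
presamples: 5              # pre-meal samples used for model initialization
seasonality: 53            # must equal pp_window_samples + presamples
burn_in_samples: 3         # observed post-meal samples before the first output
max_missing_pp: 18         # discard PPs with more missing samples (1.5 h)
gap_fill_max_minutes: 30   # training gaps strictly shorter than this are
                           # linearly interpolated; test data never is
test_days: 10              # last N calendar days form the test split
ph_minutes: [30, 45, 60, 75]   # prediction horizons
include_hypo_treatments: true  # hypoglycemia-treatment meals anchor PPs too

cluster_grid:
  nC_range: [2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19,
             20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30]
  m_grid: [1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8, 3.0]  # fuzzifier; >1
  restarts: 5              # seeded restarts per cell, best objective kept
  tol: 1.0e-05             # max membership change declaring convergence
  max_iter: 200
  min_cluster_size: 3      # smallest hard-assigned cluster allowed

sarima_grid:               # per-cluster seasonal model identification
  p_range: [1, 2, 3, 4]
  q_range: [0, 1, 2, 3, 4]
  d_range: [0, 1]
  P_range: [1, 2, 3]
  Q_range: [0, 1, 2, 3]
  D_range: [0, 1]

benchmark_grid:            # individualized ARIMA/ARIMAX comparators
  ar_range: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
  ma_range: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
  i_range: [0, 1]
  x_range: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]

seed: 0
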