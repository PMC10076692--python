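grip:
  baseline_window_s: 0.5
  min_baseline_samples: 10
  threshold_sd: 3.0
  sd_floor_N: 0.001
  sustain_s: 0.02
  max_latency_s: 5.0
  transient_s: 0.5
  target_force_N: 4.0
  digit_combine: mean
  force_floor_N: 0.01
connectome:
  alpha: 1.0
  beta: 1.0
factor:
  extraction: principal_component
  retention: parallel_analysis
  fixed_k: null
  rotation: varimax
  score_method: regression
  zscore_inputs: true
  edge_transform: log1p
  pa_permutations: 30
  pa_quantile: 0.99
  seed: 0
association:
  edge_weight_threshold: 0.4
  top_edges: 6
  vif_warn: 10.0
  lesion_membership: continuous
  composite_combine: max_abs
seed: 0
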