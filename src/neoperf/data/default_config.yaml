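# Default operating point of the perfusion-assessment pipeline.
# The protocol block encodes the clinical press/release procedure
# (5 s press, 10 s release, 3 cycles, 6 trials per subject); the
# classifier block encodes the published operating point (64 hidden
# neurons, decision threshold 0.5).
protocol:
  sampling_rate_hz: 20.0
  press_duration_s: 5.0
  release_duration_s: 10.0
  n_cycles: 3
  trials_per_subject: 6
  threshold_fraction: 0.5
  debounce_s: 0.25
  timing_tolerance: 0.2
  baseline_window_s: 3.0
  min_baseline_s: 1.0
mbll:
  source_detector_distance_cm: 1.0
  wavelengths_nm: [700.0, 910.0]
  # incident_mode: "constant" divides by incident_intensity;
  # "baseline" references the first incident_window_s of each trial.
  incident_mode: constant
  incident_intensity: [1.0, 1.0]
  incident_window_s: 1.0
  condition_number_max: 1.0e+8
  sto2_denominator_floor: 1.0e-9
indexes:
  baseline_window_s: 3.0
  press_plateau_s: 2.0
  recovery_plateau_s: 3.0
  fit_window_s: 2.0
classifier:
  n_hidden: 64
  threshold: 0.5
  width: data
  lms_step: 0.05
  lms_epochs: 200
  lms_eps: 1.0e-8
  split_level: subject
  train_per_class: 35
  test_per_class: 15
simulation:
  lead_in_s: 5.0
  tail_s: 2.0
  ramp_s: 0.5
  timing_jitter_fraction: 0.05
  amplitude_jitter_fraction: 0.05
  pressure_noise_fraction: 0.02
  press_tau_s: 1.5
  recovery_ramp_s: 2.6
  settle_tau_s: 0.8
  between_subject_fraction: 0.7
  hbt_noise_sd: 0.003
  sto2_noise_sd: 0.15
  groups: [I, II, III, IV]
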