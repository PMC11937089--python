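# Full default configuration: scenario (study conditions) and injected effects.
scenario:
  duration_s: 3600.0
  n_sections: 6
  section_s: 600.0
  speed_kmh: 80.0
  gust_spacing_m:
  - 260.0
  - 330.0
  gust_speed_kmh:
  - 0.0
  - 30.0
  car_spacing_s:
  - 4.0
  - 6.0
  unsafe_fraction:
  - 0.12
  - 0.15
  car_visible_s: 3.5
  hazard_start_m: 550.0
  condition: Manual
  seed: 0
effects:
  band_base_db:
    alpha: -118.25
    beta: -117.43
    theta: -110.03
  band_mode_delta_db:
    alpha: 1.24
    beta: 1.18
    theta: 0.55
  band_time_profile_db:
    alpha:
    - 0.0
    - 0.68
    - 1.05
    - 1.12
    - 1.18
    - 1.33
    beta:
    - 0.0
    - 0.3
    - 0.61
    - 0.5
    - 0.48
    - 0.65
    theta:
    - 0.0
    - 0.5
    - 0.83
    - 0.87
    - 0.94
    - 1.09
  band_cell_noise_db: 0.4
  perclos_base: 0.019
  perclos_mode_delta: 0.05
  perclos_time_profile:
  - 0.0
  - 0.007
  - 0.01
  - 0.012
  - 0.017
  - 0.015
  blink_rate_per_min: 6.0
  blink_duration_s: 0.3
  eye_invalid_fraction: 0.005
  sdrr_base_ms: 162.6
  sdrr_time_profile_ms:
  - 0.0
  - 10.0
  - 18.0
  - 25.0
  - 39.4
  - 30.3
  heart_rate_bpm: 72.0
  drt_median_s: 0.95
  drt_sigma_s: 0.25
  drt_pad_profile_s:
  - -0.15
  - -0.1
  - 0.0
  - 0.0
  - 0.02
  - 0.05
  hit_prob: 0.988
  driver_noise_growth: 0.25
  driver_noise_scale: 1.0
  artifact_rate_per_hour: 2.0
  artifact_amp_uv: 500.0
  artifact_duration_s: 0.3
  dropout_rate_per_hour: 3.0
  dropout_duration_s:
  - 0.2
  - 1.0
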