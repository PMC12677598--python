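{
  "n_rows": 16,
  "n_cols": 16,
  "pitch_um": 1250.0,
  "diameter_um": 850.0,
  "duration_s": 300.0,
  "fs": 1000.0,
  "fs_kin": 100.0,
  "kinematic_profile": "gait",
  "n_sources": 12,
  "spatial_scale_mm": 1.5,
  "source_amp_range": [
    1.5,
    2.5
  ],
  "baseline_hg": 0.2,
  "noise": {
    "one_over_f_scale": 5.0,
    "line_hz": 50.0,
    "line_amp": 5.0,
    "n_harmonics": 4,
    "common_mode_amp": 8.0,
    "white_rms": 0.5,
    "shared_hg_amp": 0.4,
    "shared_hg_scale_mm": 8.0
  },
  "run_config": {
    "seed": 1
  }
}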