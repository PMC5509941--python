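{
  "seed": 7,
  "n_subjects": 3,
  "grid_shape": [16, 16, 16],
  "snr": 5.0,
  "n_select_voxels": 1000,
  "feature_kinds": ["melody_abs", "melody_rel", "chroma"],
  "searchlight": {
    "repetitions": 10,
    "ridge_lambda": 1.0
  },
  "group": {
    "n_null": 12,
    "null_repetitions": 2,
    "n_bootstrap": 4000
  }
}
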