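{
  "birth_rate": 1.0,
  "gt_error_sd": 0.0,
  "n_groups": 9,
  "n_species": 133,
  "root_log10_gt": 0.0,
  "seed": 0,
  "sigma2_bm": 0.075,
  "sigma2_gt_bm": 0.15,
  "true_intercept": -8.5,
  "true_slope": -0.71
}
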