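{
  "alpha0_per_Gy": 0.454,
  "beta0_per_Gy2": 0.0,
  "r_d_um": 0.3,
  "z0_Gy": 2.51,
  "r_n_um": 7.8,
  "method": "saturation"
}
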