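{
  "a1": 18500.0,
  "a2": 5.38,
  "eta": 0.604,
  "kappa": 0.106,
  "z_thre_Gy": "inf",
  "n_population": 700000.0
}
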