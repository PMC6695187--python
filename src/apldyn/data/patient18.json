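{
  "patient": "18",
  "r_N": 2193.2,
  "mu_N": 2.88,
  "r_A": 3.8808,
  "mu_A": 0.6648,
  "K_A": 25000.0,
  "beta1": 0.001511,
  "beta2": 0.003569,
  "beta3": 0.289005,
  "gamma": 0.093906
}
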