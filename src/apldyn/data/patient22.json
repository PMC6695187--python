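{
  "patient": "22",
  "r_N": 1071.7,
  "mu_N": 2.88,
  "r_A": 3.8808,
  "mu_A": 0.6648,
  "K_A": 25000.0,
  "beta1": 0.006588,
  "beta2": 0.003259,
  "beta3": 0.173926,
  "gamma": 0.034529
}
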