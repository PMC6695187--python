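{
  "mu_N": 2.88,
  "r_A": 3.8808,
  "mu_A": 0.6648,
  "K_A": 25000.0,
  "tau": 0.623054,
  "dose_per_bsa": 60.0,
  "dose_days": [2.0, 4.0, 6.0, 8.0],
  "bsa": 1.82,
  "atra_start": 0.0,
  "atra_end": 30.0,
  "half_life_hours": 26.7,
  "intervals": {
    "r_N": [2880.0, 23040.0],
    "beta1": [0.0, 0.03],
    "beta2": [0.0, 0.005],
    "beta3": [0.0, 1.0],
    "gamma": [0.0, 0.2]
  }
}
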