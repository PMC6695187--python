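{
  "denominator": 38,
  "counts": {
    "male": 20,
    "female": 18,
    "bleeding_episode": 14,
    "treatment_toxicity": 10,
    "cardiac_toxicity": 4,
    "febrile_neutropenia": 4,
    "other_toxicity": 2,
    "deaths": 9,
    "deaths_pre_remission": 5,
    "relapse": 6,
    "relapse_during_maintenance": 4,
    "risk_high": 9,
    "risk_intermediate": 26,
    "risk_low": 3
  },
  "trial_comparison_counts": {
    "male": 20,
    "female": 18,
    "bleeding": 14,
    "remission": 33,
    "death": 9,
    "death_during_induction": 4,
    "relapse": 6,
    "risk_high": 9,
    "risk_intermediate": 26,
    "risk_low": 3
  }
}
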