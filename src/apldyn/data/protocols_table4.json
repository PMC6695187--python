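{
  "chemo_variants": [
    {"label": "P0", "dose_per_bsa": 60.0, "dose_days": [2, 4, 6, 8], "atra_start": 0.0, "atra_end": 30.0, "atra_scale": 1.0},
    {"label": "P1", "dose_per_bsa": 30.0, "dose_days": [2, 3, 4, 5, 6, 7, 8, 9], "atra_start": 0.0, "atra_end": 30.0, "atra_scale": 1.0},
    {"label": "P2", "dose_per_bsa": 60.0, "dose_days": [2, 6], "atra_start": 0.0, "atra_end": 30.0, "atra_scale": 1.0},
    {"label": "P3", "dose_per_bsa": 60.0, "dose_days": [2, 4], "atra_start": 0.0, "atra_end": 30.0, "atra_scale": 1.0},
    {"label": "P4", "dose_per_bsa": 30.0, "dose_days": [2, 3, 4, 5], "atra_start": 0.0, "atra_end": 30.0, "atra_scale": 1.0},
    {"label": "P5", "dose_per_bsa": 30.0, "dose_days": [2, 4, 6, 8], "atra_start": 0.0, "atra_end": 30.0, "atra_scale": 1.0},
    {"label": "P6", "dose_per_bsa": 60.0, "dose_days": [2], "atra_start": 0.0, "atra_end": 30.0, "atra_scale": 1.0},
    {"label": "P7", "dose_per_bsa": 30.0, "dose_days": [2], "atra_start": 0.0, "atra_end": 30.0, "atra_scale": 1.0},
    {"label": "P8", "dose_per_bsa": 60.0, "dose_days": [], "atra_start": 0.0, "atra_end": 30.0, "atra_scale": 1.0}
  ],
  "atra_variants": [
    {"label": "Q1", "dose_per_bsa": 60.0, "dose_days": [2, 4, 6, 8], "atra_start": 0.0, "atra_end": 15.0, "atra_scale": 1.0},
    {"label": "Q2", "dose_per_bsa": 60.0, "dose_days": [2, 4, 6, 8], "atra_start": 0.0, "atra_end": 30.0, "atra_scale": 0.5},
    {"label": "Q3", "dose_per_bsa": 60.0, "dose_days": [2, 4, 6, 8], "atra_start": 0.0, "atra_end": 15.0, "atra_scale": 2.0},
    {"label": "Q4", "dose_per_bsa": 60.0, "dose_days": [2, 4, 6, 8], "atra_start": 0.0, "atra_end": 30.0, "atra_scale": 0.0}
  ]
}
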