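name: fig6_km1_destab
model_variant: mm
overrides:
  k4: 0.1
  Km1:
  - 0.1
  - 1.0
  - 10.0
  - 100.0
  - 1000.0
dose_axis: X
dose_lower: 0.01
dose_upper: 100.0
step_percent: 1.0
readouts: null
total: null
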