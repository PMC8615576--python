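name: fig5_emergence
model_variant: mm
overrides:
  Km1: 100.0
  Km2: 100.0
  k4:
  - 0.0001
  - 0.001
  - 0.01
  - 0.1
dose_axis: X
dose_lower: 0.01
dose_upper: 100.0
step_percent: 1.0
readouts: null
total: null
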