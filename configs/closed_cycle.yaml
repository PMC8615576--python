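name: closed_cycle
model_variant: mm
overrides:
  k0: 0.0
  k3: 0.0
  k4: 0.0
dose_axis: X
dose_lower: 0.01
dose_upper: 100.0
step_percent: 1.0
readouts: null
total: 100.0
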