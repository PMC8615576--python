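name: fig8_k0_sweep_k2zero
model_variant: mm
overrides:
  X: 1.0
  k2: 0.0
  k4: 1.0
dose_axis: k0
dose_lower: 0.01
dose_upper: 100.0
step_percent: 1.0
readouts: null
total: null
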