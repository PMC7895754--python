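events: []
oxygen_percent: 2.0
duration: 48.0
dose_scale: 1.0
interventions:
- parameter: k26
  multiplier: 0.1
  onset: 0.0
medium_volume_ml: 1.0e-06
molecular_weights: {}
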