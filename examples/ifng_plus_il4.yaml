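events:
- time: 0.0
  species: IFNG_ext
  dose: 10.0
  units: ng/mL
- time: 0.0
  species: IL4_ext
  dose: 10.0
  units: ng/mL
oxygen_percent: 21.0
duration: 48.0
dose_scale: 1.0
interventions: []
medium_volume_ml: 1.0e-06
molecular_weights: {}
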