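# AFM pipeline on a synthetic apo -> transition-cell image series.
synthetic_series:
  - {index: 0, lattice: {c_length: 9.3, roughness_sd: 0.08}}
  - {index: 1, lattice: {c_length: 9.3, roughness_sd: 0.08}}
  - {index: 2, lattice: {c_length: 7.9, roughness_sd: 0.08}}
  - {index: 3, lattice: {c_length: 7.9, roughness_sd: 0.08}}
seed: 1
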