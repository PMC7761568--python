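condition:
  Antigens: 1
  CD80_86: 1
  MHCI: 1
  PD1_L: 1
meta:
  cell_type: CD8
  description: CD8+ cell engaging both the CTLA4 axis and PD1
  localization: none
  name: CTLA4_PD1_coexpression
perturbations: {}
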