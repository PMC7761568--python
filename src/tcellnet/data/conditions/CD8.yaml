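condition:
  Antigens: 1
  MHCI: 1
meta:
  cell_type: CD8
  description: 'CD8+ cell: MHCI presented'
  localization: none
  name: CD8
perturbations: {}
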