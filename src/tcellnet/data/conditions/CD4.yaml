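condition:
  Antigens: 1
  MHCII: 1
meta:
  cell_type: CD4
  description: 'CD4+ cell: MHCII presented'
  localization: none
  name: CD4
perturbations: {}
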