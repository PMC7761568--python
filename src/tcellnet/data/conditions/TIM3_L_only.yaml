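condition:
  Antigens: 1
  MHCI: 1
  MHCII: 1
  TIM3_L: 1
meta:
  cell_type: generic
  description: TIM3_L (ligand for TIM3) only
  localization: none
  name: TIM3_L_only
perturbations: {}
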