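condition:
  Antigens: 1
  MHCI: 1
  MHCII: 1
  PD1_L: 1
meta:
  cell_type: generic
  description: PD1_L (ligand for PD1) only
  localization: none
  name: PD1_L_only
perturbations: {}
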