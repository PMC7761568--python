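condition:
  Antigens: 1
  MHCI: 1
  MHCII: 1
  TIGIT_L: 1
meta:
  cell_type: generic
  description: TIGIT_L (CD155/CD112, ligand for TIGIT or CD226) only
  localization: none
  name: TIGIT_L_only
perturbations: {}
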