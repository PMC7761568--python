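condition:
  Antigens: 1
  MHCI: 1
  MHCII: 1
meta:
  cell_type: generic
  description: antigen recognition only, no checkpoint ligand
  localization: none
  name: no_checkpoint
perturbations: {}
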