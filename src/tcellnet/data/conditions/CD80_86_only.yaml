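condition:
  Antigens: 1
  CD80_86: 1
  MHCI: 1
  MHCII: 1
meta:
  cell_type: generic
  description: CD80/86 (ligand for CTLA4 or CD28) only
  localization: none
  name: CD80_86_only
perturbations: {}
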