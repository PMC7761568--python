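condition:
  Antigens: 1
  CD80_86: 1
  ICOS_L: 1
  MHCI: 1
  TNFRs_L: 1
meta:
  cell_type: CD8
  description: 'lymph-node priming: CTLA4, ICOS, TNFRs active'
  localization: LN
  name: LN
perturbations: {}
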