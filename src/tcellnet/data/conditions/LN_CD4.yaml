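condition:
  Antigens: 1
  CD80_86: 1
  ICOS_L: 1
  MHCII: 1
  TNFRs_L: 1
meta:
  cell_type: CD4
  description: lymph-node priming of a CD4+ cell
  localization: LN
  name: LN_CD4
perturbations: {}
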