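condition:
  Antigens: 1
  CD80_86: 1
  ICOS_L: 1
  LAG3_L: 1
  MHCII: 1
  PD1_L: 1
  TIGIT_L: 1
  TIM3_L: 1
  TNFRs_L: 1
meta:
  cell_type: CD4
  description: 'TME activation of a CD4+ cell: CD28-dependent (CD80/86 present) but
    CTLA4 not expressed'
  localization: TME
  name: TME_CD4
perturbations:
  CTLA4: 0
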