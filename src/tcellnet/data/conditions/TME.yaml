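condition:
  Antigens: 1
  ICOS_L: 1
  LAG3_L: 1
  MHCI: 1
  PD1_L: 1
  TIGIT_L: 1
  TIM3_L: 1
  TNFRs_L: 1
meta:
  cell_type: CD8
  description: 'tumour microenvironment: ICOS, TNFRs, PD1, TIGIT, LAG3, TIM3 active;
    CTLA4 not expressed'
  localization: TME
  name: TME
perturbations:
  CTLA4: 0
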