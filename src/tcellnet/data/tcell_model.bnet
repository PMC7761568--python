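# T-cell activation network under immune-checkpoint control
# Inhibitory-bias logical rules; see docs/methods.md for the
# reconstruction conventions and per-rule rationale.
targets, factors
# condition input, constant along trajectories
# kind: input
Antigens, Antigens
# condition input, constant along trajectories
# kind: input
MHCI, MHCI
# condition input, constant along trajectories
# kind: input
MHCII, MHCII
# condition input, constant along trajectories
# kind: input
CD80_86, CD80_86
# condition input, constant along trajectories
# kind: input
PD1_L, PD1_L
# condition input, constant along trajectories
# kind: input
TIGIT_L, TIGIT_L
# condition input, constant along trajectories
# kind: input
TIM3_L, TIM3_L
# condition input, constant along trajectories
# kind: input
ICOS_L, ICOS_L
# condition input, constant along trajectories
# kind: input
TNFRs_L, TNFRs_L
# condition input, constant along trajectories
# kind: input
IFNG, IFNG
# condition input, constant along trajectories
# kind: input
IL12, IL12
# condition input, constant along trajectories
# kind: input
IL27, IL27
# condition input, constant along trajectories
# kind: input
TGFb, TGFb
# LAG3 ligand; expression unstable under Tbet
LAG3_L, LAG3_L & !Tbet
# co-receptor engaged by MHCII (CD4+ cells)
CD4, MHCII
# co-receptor engaged by MHCI (CD8+ cells)
CD8, MHCI
# proximal kinases; self-sustaining once active, TIM3 blocks their initial activation
LCK_FYN, (CD4 | CD8) & (LCK_FYN | !TIM3)
# antigen receptor; active with antigen and LCK/FYN, silenced by SHP phosphatases
TCR, Antigens & LCK_FYN & !SHP
# induced by activation or FOXP3 (positive loop), engaged and self-sustaining while CD80/86 present
CTLA4, CD80_86 & (CTLA4 | FOXP3 | LAT)
# costimulation; outcompeted by CTLA4 for CD80/86 and dephosphorylated by PD1-recruited SHP
CD28, CD80_86 & !CTLA4 & !SHP
# expression promoted by FOXO1 (or IL27/MAF-PRDM1), repressed by Tbet
PD1, PD1_L & (FOXO1 | MAF_PRDM1) & !Tbet
# inhibitory receptor for CD155/CD112; mutually exclusive with CD226
TIGIT, TIGIT_L & !CD226
# costimulatory receptor for the same ligands; requires TCR engagement, excluded once SHIP1 signalling is set
CD226, TIGIT_L & TCR & !SHIP1
# phosphatase recruited by engaged TIGIT
SHIP1, TIGIT & !CD226
# activation-induced receptor; expressed on IL2-producing activated cells
LAG3, LAG3_L & IL2
# engaged whenever its ligand is present
TIM3, TIM3_L
# activation-induced costimulator
ICOS, ICOS_L & LAT
# activation-induced TNF-receptor family costimulators
TNFRs, TNFRs_L & LAT
# SHP1/2 phosphatases recruited by inhibitory checkpoints
SHP, PD1 | LAG3 | CTLA4
# LAT signalosome (incl. VAV, PLCG) downstream of TCR
LAT, TCR
# calcium/NFAT pathway
Ca_NFAT, LAT
# MAPK pathway (p38, JNK, ERK)
MAPK, LAT
# NFkB pathway; boosted by TNFRs
NFkB, LAT | TNFRs
# PI3K recruited at TCR and costimulatory receptors; blocked by SHIP1 (and by SHP through its receptor sources)
PI3K, (TCR | CD28 | ICOS | CD226) & !SHIP1
# AKT downstream of PI3K
AKT, PI3K
# constitutively active kinase, inactivated by AKT
GSK3, !AKT
# nuclear in naive cells, exported upon AKT phosphorylation
FOXO1, !AKT
# STAT1 downstream of IFNG and IL27
STAT1, IFNG | IL27
# STAT3 downstream of IL27
STAT3, IL27
# STAT4 downstream of IL12
STAT4, IL12
# SMAD downstream of TGFb
SMAD, TGFb
# NFIL3 induced by STAT3
NFIL3, STAT3
# MAF/PRDM1 induced by IL27; drives checkpoint expression
MAF_PRDM1, IL27
# activated through the PI3K-GSK3 axis or STAT1/STAT4; restrained by STAT3
Tbet, (!GSK3 | STAT1 | STAT4) & !STAT3
# IL2 expression requires the three TCR pathways together
IL2, Ca_NFAT & MAPK & NFkB
# induced by FOXO1, CTLA4, TGFb/SMAD or STAT1; blocked by PI3K and by the IL27/STAT3/NFIL3 axis
FOXP3, (FOXO1 | CTLA4 | SMAD | STAT1) & !PI3K & !STAT3 & !NFIL3
# clonal expansion: IL2 plus the PI3K survival arm
# kind: phenotype
Proliferation_Survival, IL2 & PI3K
# Th1/cytotoxic differentiation: Tbet with NFAT signalling
# kind: phenotype
Th1_CTL, Tbet & Ca_NFAT
# induced regulatory differentiation: FOXP3 with FOXO1
# kind: phenotype
Treg, FOXP3 & FOXO1
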