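"""The T-cell activation network under immune-checkpoint control.

The model captures TCR signalling (antigen recognition via MHC and the
CD4/CD8 co-receptors, the LCK/FYN kinases, the LAT signalosome and the
Ca/NFAT, MAPK, NFkB and PI3K/AKT pathways), its modulation by five
inhibitory checkpoints (CTLA4, PD1, TIGIT, LAG3, TIM3) and three
activating ones (CD28, ICOS, TNFRs, plus the CD226 co-receptor that
competes with TIGIT for CD155/CD112), and the cytokine axes (IFNG, IL12,
IL27, TGFb) that converge on the FOXP3/FOXO1/Tbet transcription-factor
hub.  Read-outs are three phenotype nodes: ``Proliferation_Survival``
(IL2- and PI3K-dependent clonal expansion), ``Th1_CTL`` (Tbet-driven
effector differentiation) and ``Treg`` (FOXP3/FOXO1-driven regulatory
differentiation).

Rules follow an inhibitory bias: alternative activators combine with OR,
obligatory partners with AND, and every active inhibitor vetoes its
target (AND NOT).  Checkpoint-inhibitor treatments are perturbations
that force a receptor node to 0; overexpression forces it to 1.

Cell conditions reproduce the model's contexts: single-checkpoint ligand
panels on a generic T cell, lymph-node (LN) priming with the
CTLA4/ICOS/TNFRs repertoire, tumour-microenvironment (TME) effector
activation with the PD1/TIGIT/LAG3/TIM3/ICOS/TNFRs repertoire (CTLA4 is
not expressed in the TME), and CD4+/CD8+ cell types selected through
MHCII/MHCI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping

from .logic import BooleanNetwork, Const, NodeSpec, parse_rule
from .stochastic import InitialConditionSpec

__all__ = [
    "build_tcell_network",
    "CellCondition",
    "Perturbation",
    "CONDITIONS",
    "TREATMENTS",
    "PHENOTYPE_NODES",
    "INPUT_NODES",
    "NAIVE_ACTIVE_NODES",
    "condition_initial_spec",
    "condition_network",
    "apply_perturbations",
    "model_provenance",
]

PHENOTYPE_NODES = ("Proliferation_Survival", "Th1_CTL", "Treg")

#: Ligand and cytokine inputs; value clamped by the cell condition.
INPUT_NODES = ("Antigens", "MHCI", "MHCII", "CD80_86", "PD1_L", "TIGIT_L",
               "TIM3_L", "ICOS_L", "TNFRs_L", "IFNG", "IL12", "IL27", "TGFb")

#: Internal nodes that are constitutively active in a naive T cell and
#: therefore start at 1 (GSK3 kinase activity and nuclear FOXO1 are both
#: present in resting cells; their rules switch them off once PI3K/AKT
#: signalling is established).
NAIVE_ACTIVE_NODES = ("GSK3", "FOXO1")

# node -> (rule, kind, provenance note written into the shipped file)
_MODEL: dict[str, tuple[str, str, str]] = {
    # ---- inputs -----------------------------------------------------------
    **{nm: (nm, "input", "condition input, constant along trajectories")
       for nm in INPUT_NODES},
    # LAG3_L is a ligand but not constant: Tbet destabilizes its
    # expression, which is why LAG3 ligands alone do not inhibit.
    "LAG3_L": ("LAG3_L & !Tbet", "internal",
               "LAG3 ligand; expression unstable under Tbet"),
    # ---- antigen recognition ---------------------------------------------
    "CD4": ("MHCII", "internal", "co-receptor engaged by MHCII (CD4+ cells)"),
    "CD8": ("MHCI", "internal", "co-receptor engaged by MHCI (CD8+ cells)"),
    "LCK_FYN": ("(CD4 | CD8) & (LCK_FYN | !TIM3)", "internal",
                "proximal kinases; self-sustaining once active, TIM3 blocks"
                " their initial activation"),
    "TCR": ("Antigens & LCK_FYN & !SHP", "internal",
            "antigen receptor; active with antigen and LCK/FYN, silenced by"
            " SHP phosphatases"),
    # ---- checkpoint receptors --------------------------------------------
    "CTLA4": ("CD80_86 & (CTLA4 | FOXP3 | LAT)", "internal",
              "induced by activation or FOXP3 (positive loop), engaged and"
              " self-sustaining while CD80/86 present"),
    "CD28": ("CD80_86 & !CTLA4 & !SHP", "internal",
             "costimulation; outcompeted by CTLA4 for CD80/86 and"
             " dephosphorylated by PD1-recruited SHP"),
    "PD1": ("PD1_L & (FOXO1 | MAF_PRDM1) & !Tbet", "internal",
            "expression promoted by FOXO1 (or IL27/MAF-PRDM1), repressed by"
            " Tbet"),
    "TIGIT": ("TIGIT_L & !CD226", "internal",
              "inhibitory receptor for CD155/CD112; mutually exclusive with"
              " CD226"),
    "CD226": ("TIGIT_L & TCR & !SHIP1", "internal",
              "costimulatory receptor for the same ligands; requires TCR"
              " engagement, excluded once SHIP1 signalling is set"),
    "SHIP1": ("TIGIT & !CD226", "internal",
              "phosphatase recruited by engaged TIGIT"),
    "LAG3": ("LAG3_L & IL2", "internal",
             "activation-induced receptor; expressed on IL2-producing"
             " activated cells"),
    "TIM3": ("TIM3_L", "internal", "engaged whenever its ligand is present"),
    "ICOS": ("ICOS_L & LAT", "internal",
             "activation-induced costimulator"),
    "TNFRs": ("TNFRs_L & LAT", "internal",
              "activation-induced TNF-receptor family costimulators"),
    # ---- proximal signalling ---------------------------------------------
    "SHP": ("PD1 | LAG3 | CTLA4", "internal",
            "SHP1/2 phosphatases recruited by inhibitory checkpoints"),
    "LAT": ("TCR", "internal",
            "LAT signalosome (incl. VAV, PLCG) downstream of TCR"),
    "Ca_NFAT": ("LAT", "internal", "calcium/NFAT pathway"),
    "MAPK": ("LAT", "internal", "MAPK pathway (p38, JNK, ERK)"),
    "NFkB": ("LAT | TNFRs", "internal", "NFkB pathway; boosted by TNFRs"),
    "PI3K": ("(TCR | CD28 | ICOS | CD226) & !SHIP1", "internal",
             "PI3K recruited at TCR and costimulatory receptors; blocked by"
             " SHIP1 (and by SHP through its receptor sources)"),
    "AKT": ("PI3K", "internal", "AKT downstream of PI3K"),
    "GSK3": ("!AKT", "internal",
             "constitutively active kinase, inactivated by AKT"),
    "FOXO1": ("!AKT", "internal",
              "nuclear in naive cells, exported upon AKT phosphorylation"),
    # ---- cytokine signalling ---------------------------------------------
    "STAT1": ("IFNG | IL27", "internal", "STAT1 downstream of IFNG and IL27"),
    "STAT3": ("IL27", "internal", "STAT3 downstream of IL27"),
    "STAT4": ("IL12", "internal", "STAT4 downstream of IL12"),
    "SMAD": ("TGFb", "internal", "SMAD downstream of TGFb"),
    "NFIL3": ("STAT3", "internal", "NFIL3 induced by STAT3"),
    "MAF_PRDM1": ("IL27", "internal",
                  "MAF/PRDM1 induced by IL27; drives checkpoint expression"),
    # ---- transcription-factor hub ----------------------------------------
    "Tbet": ("(!GSK3 | STAT1 | STAT4) & !STAT3", "internal",
             "activated through the PI3K-GSK3 axis or STAT1/STAT4;"
             " restrained by STAT3"),
    "IL2": ("Ca_NFAT & MAPK & NFkB", "internal",
            "IL2 expression requires the three TCR pathways together"),
    "FOXP3": ("(FOXO1 | CTLA4 | SMAD | STAT1) & !PI3K & !STAT3 & !NFIL3",
              "internal",
              "induced by FOXO1, CTLA4, TGFb/SMAD or STAT1; blocked by PI3K"
              " and by the IL27/STAT3/NFIL3 axis"),
    # ---- phenotypes -------------------------------------------------------
    "Proliferation_Survival": ("IL2 & PI3K", "phenotype",
                               "clonal expansion: IL2 plus the PI3K survival"
                               " arm"),
    "Th1_CTL": ("Tbet & Ca_NFAT", "phenotype",
                "Th1/cytotoxic differentiation: Tbet with NFAT signalling"),
    "Treg": ("FOXP3 & FOXO1", "phenotype",
             "induced regulatory differentiation: FOXP3 with FOXO1"),
}


def shipped_model_path() -> Path:
    """Path of the model file shipped with the package (BoolNet dialect)."""
    return Path(__file__).parent / "data" / "tcell_model.bnet"


def shipped_condition_dir() -> Path:
    """Directory of the shipped per-condition scenario configurations."""
    return Path(__file__).parent / "data" / "conditions"


def build_tcell_network() -> BooleanNetwork:
    """Construct the validated T-cell checkpoint network."""
    nodes = [NodeSpec(nm, parse_rule(rule), kind)
             for nm, (rule, kind, _) in _MODEL.items()]
    return BooleanNetwork(nodes)


def model_provenance() -> dict[str, str]:
    """Per-node provenance notes (written as comments in the model file)."""
    return {nm: note for nm, (_, _, note) in _MODEL.items()}


# --------------------------------------------------------------------------
# Perturbations (treatments, overexpression, repertoire clamps)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Perturbation:
    """A node forced to a constant value (knock-out 0 or overexpression 1)."""

    node: str
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("forced value must be 0 or 1")


#: Checkpoint-inhibitor treatments force the receptor to 0; the LAG3
#: overexpression control forces it to 1.
TREATMENTS: Mapping[str, tuple[Perturbation, ...]] = MappingProxyType({
    "anti-CTLA4": (Perturbation("CTLA4", 0),),
    "anti-PD1": (Perturbation("PD1", 0),),
    "anti-TIGIT": (Perturbation("TIGIT", 0),),
    "anti-LAG3": (Perturbation("LAG3", 0),),
    "anti-TIM3": (Perturbation("TIM3", 0),),
    "anti-PD1+anti-CTLA4": (Perturbation("PD1", 0), Perturbation("CTLA4", 0)),
    "LAG3-overexpression": (Perturbation("LAG3", 1),),
})


def apply_perturbations(net: BooleanNetwork,
                        perturbations: Iterable[Perturbation | tuple[str, int]],
                        ) -> BooleanNetwork:
    """A perturbed copy of ``net`` with forced nodes' rules set constant."""
    forced: dict[str, int] = {}
    for p in perturbations:
        node, value = (p.node, p.value) if isinstance(p, Perturbation) else p
        if node not in net:
            raise KeyError(f"unknown node {node!r}")
        if node in forced and forced[node] != value:
            raise ValueError(f"conflicting perturbations on {node!r}")
        forced[node] = value
    return net.replace_rules({nm: Const(v) for nm, v in forced.items()})


# --------------------------------------------------------------------------
# Cell conditions (the model's context catalogue)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellCondition:
    """A named context: which ligands/cytokines are present.

    ``active_inputs`` are clamped to 1 (all other inputs to 0).
    ``forced`` carries receptor-repertoire clamps that are part of the
    context itself — the TME conditions force CTLA4 to 0 because
    tumour-infiltrating effector cells do not express it.
    """

    name: str
    active_inputs: frozenset[str]
    cell_type: str = "generic"        # "CD4" | "CD8" | "generic"
    localization: str = "none"        # "LN" | "TME" | "none"
    forced: Mapping[str, int] = field(default_factory=dict)
    description: str = ""

    def with_cytokines(self, cytokines: Iterable[str]) -> "CellCondition":
        cyt = frozenset(cytokines)
        unknown = cyt - {"IFNG", "IL12", "IL27", "TGFb"}
        if unknown:
            raise KeyError(f"unknown cytokines: {sorted(unknown)}")
        suffix = "+" + "+".join(sorted(cyt)) if cyt else ""
        return CellCondition(self.name + suffix, self.active_inputs | cyt,
                             self.cell_type, self.localization, self.forced,
                             self.description)


def _antigen(cell_type: str) -> frozenset[str]:
    mhc = {"CD4": ("MHCII",), "CD8": ("MHCI",),
           "generic": ("MHCI", "MHCII")}[cell_type]
    return frozenset(("Antigens", *mhc))


def _cond(name: str, extra: Iterable[str] = (), cell_type: str = "generic",
          localization: str = "none", forced: Mapping[str, int] | None = None,
          description: str = "") -> CellCondition:
    return CellCondition(name, _antigen(cell_type) | frozenset(extra),
                         cell_type, localization,
                         MappingProxyType(dict(forced or {})), description)


#: The shipped condition catalogue.  The single-ligand panel uses a
#: generic T cell (both MHC classes presented); LN and TME encode the
#: two-step checkpoint repertoires; CD4/CD8 select the co-receptor.
CONDITIONS: Mapping[str, CellCondition] = MappingProxyType({
    c.name: c for c in [
        _cond("no_checkpoint",
              description="antigen recognition only, no checkpoint ligand"),
        _cond("CD80_86_only", ["CD80_86"],
              description="CD80/86 (ligand for CTLA4 or CD28) only"),
        _cond("PD1_L_only", ["PD1_L"],
              description="PD1_L (ligand for PD1) only"),
        _cond("TIGIT_L_only", ["TIGIT_L"],
              description="TIGIT_L (CD155/CD112, ligand for TIGIT or CD226)"
                          " only"),
        _cond("TIM3_L_only", ["TIM3_L"],
              description="TIM3_L (ligand for TIM3) only"),
        _cond("LAG3_L_only", ["LAG3_L"],
              description="LAG3_L (ligand for LAG3) only"),
        _cond("CTLA4_PD1_coexpression", ["CD80_86", "PD1_L"], "CD8",
              description="CD8+ cell engaging both the CTLA4 axis and PD1"),
        _cond("LN", ["CD80_86", "ICOS_L", "TNFRs_L"], "CD8", "LN",
              description="lymph-node priming: CTLA4, ICOS, TNFRs active"),
        _cond("TME", ["PD1_L", "TIGIT_L", "LAG3_L", "TIM3_L", "ICOS_L",
                      "TNFRs_L"], "CD8", "TME",
              forced={"CTLA4": 0},
              description="tumour microenvironment: ICOS, TNFRs, PD1, TIGIT,"
                          " LAG3, TIM3 active; CTLA4 not expressed"),
        _cond("LN_CD4", ["CD80_86", "ICOS_L", "TNFRs_L"], "CD4", "LN",
              description="lymph-node priming of a CD4+ cell"),
        _cond("TME_CD4", ["CD80_86", "PD1_L", "TIGIT_L", "LAG3_L", "TIM3_L",
                          "ICOS_L", "TNFRs_L"], "CD4", "TME",
              forced={"CTLA4": 0},
              description="TME activation of a CD4+ cell: CD28-dependent"
                          " (CD80/86 present) but CTLA4 not expressed"),
        _cond("CD8", [], "CD8", description="CD8+ cell: MHCI presented"),
        _cond("CD4", [], "CD4", description="CD4+ cell: MHCII presented"),
    ]
})


def condition_initial_spec(cond: CellCondition,
                           net: BooleanNetwork | None = None,
                           ) -> InitialConditionSpec:
    """Initial values encoding a cell condition.

    Active inputs are set to 1 (and stay there: input rules are the
    identity), all other inputs to 0.  Internal nodes start at 0 except
    the constitutively active GSK3 and FOXO1, the co-receptors CD4/CD8
    (engaged from the start according to the MHC class presented) and
    the LAG3 ligand when the condition provides it.
    """
    net = net or build_tcell_network()
    unknown = cond.active_inputs - set(net.names)
    if unknown:
        raise KeyError(f"unknown nodes in condition: {sorted(unknown)}")
    values = {nm: 0 for nm in net.names}
    for nm in cond.active_inputs:
        values[nm] = 1
    for nm in NAIVE_ACTIVE_NODES:
        values[nm] = 1
    values["CD4"] = values["MHCII"]
    values["CD8"] = values["MHCI"]
    for nm, v in cond.forced.items():
        values[nm] = v
    return InitialConditionSpec(values=values)


def condition_network(cond: CellCondition,
                      treatments: Iterable[Perturbation | tuple[str, int]] = (),
                      net: BooleanNetwork | None = None) -> BooleanNetwork:
    """The network with the condition's repertoire clamps and treatments."""
    net = net or build_tcell_network()
    perts: list[Perturbation] = [Perturbation(nm, v)
                                 for nm, v in cond.forced.items()]
    for p in treatments:
        perts.append(p if isinstance(p, Perturbation) else Perturbation(*p))
    # a treatment may override a repertoire clamp only when it agrees;
    # anti-CTLA4 on a TME condition (CTLA4 already absent) is a no-op
    merged: dict[str, int] = {}
    for p in perts:
        if p.node in merged and merged[p.node] != p.value:
            raise ValueError(f"conflicting perturbations on {p.node!r}")
        merged[p.node] = p.value
    return apply_perturbations(net, [Perturbation(nm, v)
                                     for nm, v in merged.items()])
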