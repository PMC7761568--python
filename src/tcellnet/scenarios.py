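"""In-silico experiment protocols and directional pass/fail comparisons.

Each protocol simulates a set of cell conditions and treatments with the
stochastic engine, extracts the asymptotic phenotype distribution per
condition, and grades the outcome against the qualitative expectations
for checkpoint-inhibitor therapy:

``single_checkpoint_panel``
    Each inhibitory checkpoint's ligand activated one by one on a
    generic T cell; reports inhibition strengths relative to the
    checkpoint-free baseline.

``two_step_protocol``
    T-cell response as two independent stages — priming in the lymph
    node (CTLA4/ICOS/TNFRs repertoire) and effector activation in the
    tumour microenvironment (PD1/TIGIT/LAG3/TIM3/ICOS/TNFRs) — with a
    combined readout: the product of the LN proliferation probability
    and the TME phenotype probability, operationalizing "no effector
    response without successful priming".

``coexpression_panel``
    CD8+ subpopulations co-expressing PD1 with or without CTLA4, under
    each therapy; captures CTLA4 dominance and therapy synergy.

``cytokine_panel``
    CD4+ TME activation under anti-PD1, with IFNG / IL12 / IL27 / TGFb
    added one at a time; reports Th1/Treg ratios.

All simulations within a protocol share one seed, so a treatment that
cannot act in a context (e.g. anti-PD1 in the lymph node, where no PD1
ligand is present) reproduces the untreated trajectories bit for bit
and "no effect" verdicts hold exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .logic import BooleanNetwork
from .stochastic import (InitialConditionSpec, PhenotypeDistribution,
                         SimulationConfig, TrajectoryEnsemble,
                         asymptotic_phenotypes, ensemble_converged,
                         inhibition_strength, simulate_ensemble)
from .tcell import (CONDITIONS, CellCondition, Perturbation, TREATMENTS,
                    build_tcell_network, condition_initial_spec,
                    condition_network)

__all__ = [
    "ScenarioResult",
    "DirectionalExpectation",
    "Verdict",
    "RatioValue",
    "th1_treg_ratio",
    "compare_directions",
    "simulate_condition",
    "single_checkpoint_panel",
    "two_step_protocol",
    "coexpression_panel",
    "cytokine_panel",
    "SCENARIOS",
]

TREG_EPS = 1e-6  # below this the Th1/Treg ratio is reported as undefined


# --------------------------------------------------------------------------
# Result containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioValue:
    """Th1/Treg balance; ``undefined`` when the Treg marginal is ~0."""

    value: float | None
    th1: float
    treg: float
    n: int

    @property
    def undefined(self) -> bool:
        return self.value is None

    def display(self) -> str:
        if self.undefined:
            return "undefined (Treg~0)"
        return f"{self.value:.4g}"

    def standard_error(self) -> float:
        """Delta-method SE of the ratio (0 when undefined)."""
        if self.undefined or self.value == 0:
            return 0.0
        se_t = math.sqrt(max(self.th1 * (1 - self.th1), 0.0) / self.n)
        se_r = math.sqrt(max(self.treg * (1 - self.treg), 0.0) / self.n)
        return abs(self.value) * math.sqrt((se_t / max(self.th1, TREG_EPS)) ** 2
                                           + (se_r / self.treg) ** 2)


def th1_treg_ratio(dist: PhenotypeDistribution) -> RatioValue:
    """P(Th1_CTL) / P(Treg), undefined when the denominator is ~0."""
    th1 = dist.marginal("Th1_CTL")
    treg = dist.marginal("Treg")
    value = None if treg < TREG_EPS else th1 / treg
    return RatioValue(value=value, th1=th1, treg=treg, n=dist.n)


@dataclass(frozen=True)
class DirectionalExpectation:
    """An expected change: phenotype or statistic, direction, intensity.

    ``direction`` is ``up`` / ``down`` / ``no_effect``; ``grade`` counts
    the arrows (1-3) and is only comparable within one table.
    """

    label: str                 # e.g. "LN: Proliferation"
    statistic: str             # "Proliferation_Survival" | "Th1_CTL" | "Treg" | "ratio"
    direction: str
    grade: int = 1

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "no_effect"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class Verdict:
    label: str
    expected: str
    observed: str
    passed: bool


@dataclass
class ScenarioResult:
    """Distributions, derived statistics and verdicts of one protocol."""

    scenario_id: str
    distributions: dict[str, PhenotypeDistribution]
    stats: dict[str, object] = field(default_factory=dict)
    verdicts: list[Verdict] = field(default_factory=list)
    converged: dict[str, bool] = field(default_factory=dict)
    seed: int = 0
    n_trajectories: int = 0

    @property
    def all_pass(self) -> bool:
        return all(v.passed for v in self.verdicts)

    def verdict_table(self) -> str:
        lines = ["label\texpected\tobserved\tverdict"]
        for v in self.verdicts:
            lines.append(f"{v.label}\t{v.expected}\t{v.observed}\t"
                         f"{'PASS' if v.passed else 'FAIL'}")
        return "\n".join(lines) + "\n"

    def distribution_table(self) -> str:
        labels = sorted({k for d in self.distributions.values()
                         for k in d.probs})
        lines = ["condition\t" + "\t".join(labels)]
        for name, d in self.distributions.items():
            lines.append(name + "\t" + "\t".join(
                f"{d.probs.get(lab, 0.0):.4f}" for lab in labels))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        def _stat(v: object) -> object:
            if isinstance(v, RatioValue):
                return v.display()
            if isinstance(v, float) and not math.isfinite(v):
                return str(v)
            return v

        payload = {
            "scenario": self.scenario_id,
            "seed": self.seed,
            "n_trajectories": self.n_trajectories,
            "distributions": {k: d.as_dict()
                              for k, d in self.distributions.items()},
            "converged": self.converged,
            "stats": {k: _stat(v) for k, v in self.stats.items()},
            "verdicts": [{"label": v.label, "expected": v.expected,
                          "observed": v.observed, "passed": v.passed}
                         for v in self.verdicts],
            "all_pass": self.all_pass,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# Simulation helper
# --------------------------------------------------------------------------

def simulate_condition(cond: CellCondition,
                       treatments: Iterable[Perturbation | tuple[str, int]] = (),
                       config: SimulationConfig | None = None,
                       clamps: Mapping[str, int] | None = None,
                       net: BooleanNetwork | None = None,
                       ) -> tuple[PhenotypeDistribution, TrajectoryEnsemble]:
    """Simulate a condition (with optional treatments and extra clamps).

    ``clamps`` encodes sub-population constraints (e.g. CTLA4+ cells:
    CTLA4 forced to 1); a treatment targeting the same node overrides
    the clamp, mirroring a receptor blocked by its inhibitor.
    """
    config = config or SimulationConfig()
    net = net or build_tcell_network()
    merged: dict[str, int] = dict(clamps or {})
    for p in treatments:
        node, value = (p.node, p.value) if isinstance(p, Perturbation) else p
        merged[node] = value
    cond_eff = cond if not merged else replace(
        cond, forced={**dict(cond.forced), **merged})
    pnet = condition_network(cond_eff, net=net)
    init = condition_initial_spec(cond_eff, pnet)
    ens = simulate_ensemble(pnet, init, config)
    return asymptotic_phenotypes(ens), ens


# --------------------------------------------------------------------------
# Directional comparison machinery
# --------------------------------------------------------------------------

def _stat_value(dist: PhenotypeDistribution, statistic: str
                ) -> tuple[float, float]:
    """(value, SE) of a marginal or the Th1/Treg ratio; inf for undefined
    ratios with Th1 mass (all-Th1, no-Treg limits)."""
    if statistic == "ratio":
        r = th1_treg_ratio(dist)
        if r.undefined:
            return (math.inf, 0.0) if r.th1 > TREG_EPS else (0.0, 0.0)
        return r.value, r.standard_error()
    return dist.marginal(statistic), dist.standard_error(statistic)


def compare_directions(result: Mapping[str, PhenotypeDistribution],
                       baseline: Mapping[str, PhenotypeDistribution],
                       expectations: Sequence[tuple[str, DirectionalExpectation]],
                       sigma: float = 3.0) -> list[Verdict]:
    """Grade condition-level changes against directional expectations.

    ``expectations`` pairs a condition key (present in both mappings)
    with the expected change of one statistic.  A change counts only
    beyond ``sigma`` Monte-Carlo standard errors; ``no_effect`` passes
    when the change stays within that band.
    """
    verdicts: list[Verdict] = []
    for key, exp in expectations:
        if key not in result or key not in baseline:
            raise KeyError(f"condition {key!r} missing from result or baseline")
        val, se_v = _stat_value(result[key], exp.statistic)
        base, se_b = _stat_value(baseline[key], exp.statistic)
        thresh = sigma * math.hypot(se_v, se_b)
        if math.isinf(val) or math.isinf(base):
            delta = val - base if val != base else 0.0
        else:
            delta = val - base
        if exp.direction == "up":
            ok = delta > thresh
        elif exp.direction == "down":
            ok = -delta > thresh
        else:
            ok = abs(delta) <= thresh if math.isfinite(delta) else False
        arrow = {"up": "↑" * exp.grade, "down": "↓" * exp.grade,
                 "no_effect": "no effect"}[exp.direction]
        obs = ("+inf" if math.isinf(delta) and delta > 0 else
               "-inf" if math.isinf(delta) else f"{delta:+.4f}")
        verdicts.append(Verdict(label=exp.label, expected=arrow,
                                observed=obs, passed=bool(ok)))
    return verdicts


def _se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1 - p), 0.0) / n)


# --------------------------------------------------------------------------
# Protocol: single-checkpoint panel
# --------------------------------------------------------------------------

PANEL_CONDITIONS = ("no_checkpoint", "CD80_86_only", "PD1_L_only",
                    "TIGIT_L_only", "TIM3_L_only", "LAG3_L_only")


def single_checkpoint_panel(config: SimulationConfig | None = None,
                            net: BooleanNetwork | None = None) -> ScenarioResult:
    """Each inhibitory checkpoint's ligand activated one by one.

    Reports per-condition phenotype distributions, proliferation
    inhibition strengths versus the checkpoint-free baseline, the Treg
    reduction of the TIM3 condition versus the CTLA4 condition (where
    the Treg phenotype is fully retained), and the forced-LAG3 control.
    """
    config = config or SimulationConfig()
    net = net or build_tcell_network()
    dists: dict[str, PhenotypeDistribution] = {}
    conv: dict[str, bool] = {}
    for name in PANEL_CONDITIONS:
        d, ens = simulate_condition(CONDITIONS[name], config=config, net=net)
        dists[name] = d
        conv[name] = ensemble_converged(ens)
    d, ens = simulate_condition(CONDITIONS["LAG3_L_only"],
                                treatments=TREATMENTS["LAG3-overexpression"],
                                config=config, net=net)
    dists["LAG3_forced"] = d
    conv["LAG3_forced"] = ensemble_converged(ens)

    base = dists["no_checkpoint"]
    stats: dict[str, object] = {}
    for name in ("CD80_86_only", "PD1_L_only", "TIGIT_L_only", "TIM3_L_only",
                 "LAG3_L_only", "LAG3_forced"):
        s = inhibition_strength(dists[name], base, "Proliferation_Survival")
        stats[f"inhibition_{name}"] = s.raw
    treg_ref = dists["CD80_86_only"].marginal("Treg")
    if treg_ref > 0:
        stats["treg_reduction_TIM3"] = 100.0 * (
            1.0 - dists["TIM3_L_only"].marginal("Treg") / treg_ref)

    n = config.n_trajectories
    se0 = 3 * math.hypot(_se(base.marginal("Proliferation_Survival"), n),
                         _se(dists["LAG3_L_only"].marginal(
                             "Proliferation_Survival"), n))
    checks = [
        ("CTLA4 completely inhibits proliferation",
         "P=0", f"P={dists['CD80_86_only'].marginal('Proliferation_Survival'):.4f}",
         dists["CD80_86_only"].marginal("Proliferation_Survival") <= 3 * _se(0.01, n) + 0.01),
        ("CTLA4 completely inhibits Th1",
         "P=0", f"P={dists['CD80_86_only'].marginal('Th1_CTL'):.4f}",
         dists["CD80_86_only"].marginal("Th1_CTL") <= 3 * _se(0.01, n) + 0.01),
        ("CTLA4 maintains Treg",
         "Treg retained", f"P={treg_ref:.4f}", treg_ref >= 0.5),
        ("PD1 inhibition partial and below CTLA4's",
         "0 < inhibition < 100",
         f"{stats['inhibition_PD1_L_only']:.1f}%",
         0 < stats["inhibition_PD1_L_only"] < 100
         and stats["inhibition_PD1_L_only"] < stats["inhibition_CD80_86_only"]),
        ("TIGIT inhibition partial and below CTLA4's",
         "0 < inhibition < 100",
         f"{stats['inhibition_TIGIT_L_only']:.1f}%",
         0 < stats["inhibition_TIGIT_L_only"] < 100
         and stats["inhibition_TIGIT_L_only"] < stats["inhibition_CD80_86_only"]),
        ("TIM3 reduces the Treg population by about half",
         "reduction ~50%", f"{stats.get('treg_reduction_TIM3', float('nan')):.1f}%",
         25.0 <= float(stats.get("treg_reduction_TIM3", math.nan)) <= 75.0),
        ("LAG3 ligand alone has no inhibiting activity",
         "inhibition ~0", f"{stats['inhibition_LAG3_L_only']:.2f}%",
         abs(stats["inhibition_LAG3_L_only"]) <= 100 * se0 + 1e-9),
        ("forced LAG3 inhibits",
         "inhibition > 0", f"{stats['inhibition_LAG3_forced']:.1f}%",
         stats["inhibition_LAG3_forced"] > 100 * se0),
    ]
    verdicts = [Verdict(lab, e, o, bool(p)) for lab, e, o, p in checks]
    return ScenarioResult("fig3_panel", dists, stats, verdicts, conv,
                          seed=config.seed, n_trajectories=n)


# --------------------------------------------------------------------------
# Protocol: two-step LN -> TME activation with treatments
# --------------------------------------------------------------------------

TWO_STEP_THERAPIES = ("anti-CTLA4", "anti-PD1", "anti-PD1+anti-CTLA4")

#: Directional expectations for the two-step protocol: therapy ->
#: (LN proliferation, LN Th1/Treg ratio, TME proliferation, TME ratio).
TWO_STEP_EXPECTATIONS: Mapping[str, tuple[str, str, str, str]] = {
    "anti-CTLA4": ("up", "up", "no_effect", "no_effect"),
    "anti-PD1": ("no_effect", "no_effect", "up", "up"),
    "anti-PD1+anti-CTLA4": ("up", "up", "up", "up"),
}


def two_step_protocol(config: SimulationConfig | None = None,
                      net: BooleanNetwork | None = None,
                      cell_type: str = "CD8") -> ScenarioResult:
    """LN priming and TME effector activation under each therapy.

    The two stages are simulated independently; treatments force their
    targets to 0 in both stages (a no-op in a stage whose repertoire
    does not express the target).  The combined readout multiplies the
    LN proliferation probability into the TME phenotype probabilities.
    """
    config = config or SimulationConfig()
    net = net or build_tcell_network()
    ln_name, tme_name = (("LN", "TME") if cell_type == "CD8"
                         else ("LN_CD4", "TME_CD4"))
    dists: dict[str, PhenotypeDistribution] = {}
    conv: dict[str, bool] = {}

    def stage(label: str, cond_name: str, treatment: str | None) -> None:
        t = TREATMENTS[treatment] if treatment else ()
        d, ens = simulate_condition(CONDITIONS[cond_name], treatments=t,
                                    config=config, net=net)
        dists[label] = d
        conv[label] = ensemble_converged(ens)

    stage("LN:untreated", ln_name, None)
    stage("TME:untreated", tme_name, None)
    for therapy in TWO_STEP_THERAPIES:
        stage(f"LN:{therapy}", ln_name, therapy)
        stage(f"TME:{therapy}", tme_name, therapy)

    stats: dict[str, object] = {}
    for key, d in dists.items():
        stats[f"ratio_{key}"] = th1_treg_ratio(d)
    for label in ("untreated", *TWO_STEP_THERAPIES):
        p_ln = dists[f"LN:{label}"].marginal("Proliferation_Survival")
        for ph in ("Proliferation_Survival", "Th1_CTL", "Treg"):
            stats[f"combined_{label}_{ph}"] = (
                p_ln * dists[f"TME:{label}"].marginal(ph))

    expectations: list[tuple[str, DirectionalExpectation]] = []
    result_map: dict[str, PhenotypeDistribution] = {}
    baseline_map: dict[str, PhenotypeDistribution] = {}
    for therapy in TWO_STEP_THERAPIES:
        ln_p, ln_r, tme_p, tme_r = TWO_STEP_EXPECTATIONS[therapy]
        for stage_name, p_dir, r_dir in (("LN", ln_p, ln_r),
                                         ("TME", tme_p, tme_r)):
            key = f"{stage_name}:{therapy}"
            result_map[key] = dists[key]
            baseline_map[key] = dists[f"{stage_name}:untreated"]
            expectations.append((key, DirectionalExpectation(
                f"{therapy} / {stage_name}: Proliferation",
                "Proliferation_Survival", p_dir)))
            expectations.append((key, DirectionalExpectation(
                f"{therapy} / {stage_name}: Th1_CTL/Treg ratio",
                "ratio", r_dir)))

    verdicts = compare_directions(result_map, baseline_map, expectations)

    # synergy on the combined readout: combination beats each monotherapy
    combo = stats["combined_anti-PD1+anti-CTLA4_Proliferation_Survival"]
    for mono in ("anti-CTLA4", "anti-PD1"):
        mono_val = stats[f"combined_{mono}_Proliferation_Survival"]
        verdicts.append(Verdict(
            f"combined readout: combination > {mono}",
            "greater", f"{combo:.4f} vs {mono_val:.4f}",
            bool(combo > mono_val)))
    return ScenarioResult("table3_two_step", dists, stats, verdicts, conv,
                          seed=config.seed, n_trajectories=config.n_trajectories)


# --------------------------------------------------------------------------
# Protocol: CD8+ PD1/CTLA4 co-expression subpopulations (therapy synergy)
# --------------------------------------------------------------------------

def coexpression_panel(config: SimulationConfig | None = None,
                       net: BooleanNetwork | None = None) -> ScenarioResult:
    """CD8+ cells co-expressing PD1 with or without CTLA4, per therapy.

    Captures CTLA4 dominance: in PD1+CTLA4+ cells PD1 blockade alone
    cannot reactivate proliferation, while the combination exceeds each
    monotherapy; in PD1+CTLA4- cells anti-CTLA4 has no effect and the
    combination equals anti-PD1 alone.
    """
    config = config or SimulationConfig()
    net = net or build_tcell_network()
    cond = CONDITIONS["CTLA4_PD1_coexpression"]
    subpops = {"PD1+CTLA4-": {"CTLA4": 0}, "PD1+CTLA4+": {"CTLA4": 1}}
    therapies = {"untreated": (), "anti-CTLA4": TREATMENTS["anti-CTLA4"],
                 "anti-PD1": TREATMENTS["anti-PD1"],
                 "anti-CTLA4+anti-PD1": TREATMENTS["anti-PD1+anti-CTLA4"]}
    dists: dict[str, PhenotypeDistribution] = {}
    conv: dict[str, bool] = {}
    for sub, clamp in subpops.items():
        for tname, t in therapies.items():
            d, ens = simulate_condition(cond, treatments=t, clamps=clamp,
                                        config=config, net=net)
            dists[f"{sub}:{tname}"] = d
            conv[f"{sub}:{tname}"] = ensemble_converged(ens)
    # unclamped co-expressing population (both receptors present)
    for tname, t in therapies.items():
        d, ens = simulate_condition(cond, treatments=t, config=config, net=net)
        dists[f"coexpressing:{tname}"] = d
        conv[f"coexpressing:{tname}"] = ensemble_converged(ens)

    n = config.n_trajectories

    def p(key: str, ph: str = "Proliferation_Survival") -> float:
        return dists[key].marginal(ph)

    def sig(key_a: str, key_b: str, ph: str = "Proliferation_Survival") -> float:
        return 3 * math.hypot(_se(p(key_a, ph), n), _se(p(key_b, ph), n))

    checks: list[tuple[str, str, str, bool]] = []
    # CTLA4 dominance in the co-expressing population
    checks.append((
        "coexpressing: anti-PD1 alone does not reactivate proliferation",
        "P stays 0", f"P={p('coexpressing:anti-PD1'):.4f}",
        p("coexpressing:anti-PD1") <= 0.01 + 3 * _se(0.01, n)))
    for ph in ("Proliferation_Survival", "Th1_CTL"):
        combo = p("coexpressing:anti-CTLA4+anti-PD1", ph)
        for mono in ("anti-CTLA4", "anti-PD1"):
            mv = p(f"coexpressing:{mono}", ph)
            checks.append((
                f"coexpressing {ph}: combination > {mono}",
                "greater", f"{combo:.4f} vs {mv:.4f}",
                combo - mv > sig("coexpressing:anti-CTLA4+anti-PD1",
                                 f"coexpressing:{mono}", ph)))
    # PD1+CTLA4- : anti-CTLA4 inert, anti-PD1 reactivates, combo = anti-PD1
    checks.append((
        "PD1+CTLA4-: anti-CTLA4 has no effect",
        "no effect",
        f"dP={p('PD1+CTLA4-:anti-CTLA4') - p('PD1+CTLA4-:untreated'):+.4f}",
        abs(p("PD1+CTLA4-:anti-CTLA4") - p("PD1+CTLA4-:untreated"))
        <= sig("PD1+CTLA4-:anti-CTLA4", "PD1+CTLA4-:untreated")))
    checks.append((
        "PD1+CTLA4-: anti-PD1 raises proliferation",
        "up", f"dP={p('PD1+CTLA4-:anti-PD1') - p('PD1+CTLA4-:untreated'):+.4f}",
        p("PD1+CTLA4-:anti-PD1") - p("PD1+CTLA4-:untreated")
        > sig("PD1+CTLA4-:anti-PD1", "PD1+CTLA4-:untreated")))
    checks.append((
        "PD1+CTLA4-: combination equals anti-PD1 alone",
        "equal", f"dP={p('PD1+CTLA4-:anti-CTLA4+anti-PD1') - p('PD1+CTLA4-:anti-PD1'):+.4f}",
        abs(p("PD1+CTLA4-:anti-CTLA4+anti-PD1") - p("PD1+CTLA4-:anti-PD1"))
        <= sig("PD1+CTLA4-:anti-CTLA4+anti-PD1", "PD1+CTLA4-:anti-PD1")))
    # PD1+CTLA4+ : anti-CTLA4 partial, anti-PD1 inert, combo strongest
    checks.append((
        "PD1+CTLA4+: anti-CTLA4 raises proliferation",
        "up", f"dP={p('PD1+CTLA4+:anti-CTLA4') - p('PD1+CTLA4+:untreated'):+.4f}",
        p("PD1+CTLA4+:anti-CTLA4") - p("PD1+CTLA4+:untreated")
        > sig("PD1+CTLA4+:anti-CTLA4", "PD1+CTLA4+:untreated")))
    checks.append((
        "PD1+CTLA4+: anti-PD1 alone has no effect",
        "no effect",
        f"dP={p('PD1+CTLA4+:anti-PD1') - p('PD1+CTLA4+:untreated'):+.4f}",
        abs(p("PD1+CTLA4+:anti-PD1") - p("PD1+CTLA4+:untreated"))
        <= sig("PD1+CTLA4+:anti-PD1", "PD1+CTLA4+:untreated")))
    for mono in ("anti-CTLA4", "anti-PD1"):
        checks.append((
            f"PD1+CTLA4+: combination > {mono}",
            "greater",
            f"{p('PD1+CTLA4+:anti-CTLA4+anti-PD1'):.4f} vs {p(f'PD1+CTLA4+:{mono}'):.4f}",
            p("PD1+CTLA4+:anti-CTLA4+anti-PD1") - p(f"PD1+CTLA4+:{mono}")
            > sig("PD1+CTLA4+:anti-CTLA4+anti-PD1", f"PD1+CTLA4+:{mono}")))

    verdicts = [Verdict(lab, e, o, bool(ok)) for lab, e, o, ok in checks]
    stats = {f"P_{k}": d.marginal("Proliferation_Survival")
             for k, d in dists.items()}
    return ScenarioResult("table2_cd8", dists, stats, verdicts, conv,
                          seed=config.seed, n_trajectories=n)


# --------------------------------------------------------------------------
# Protocol: cytokine modulation of the CD4+ TME response under anti-PD1
# --------------------------------------------------------------------------

CYTOKINES = ("IFNG", "IL12", "IL27", "TGFb")


def cytokine_panel(config: SimulationConfig | None = None,
                   net: BooleanNetwork | None = None) -> ScenarioResult:
    """CD4+ TME activation under anti-PD1 with single cytokines added.

    IFNG and IL12 raise the Th1/Treg ratio and create the mixed
    Treg-Th1 category; TGFb leaves the distribution unchanged; IL27
    alone extinguishes both the Th1 and the Treg phenotype.
    """
    config = config or SimulationConfig()
    net = net or build_tcell_network()
    base_cond = CONDITIONS["TME_CD4"]
    t = TREATMENTS["anti-PD1"]
    dists: dict[str, PhenotypeDistribution] = {}
    conv: dict[str, bool] = {}
    d, ens = simulate_condition(base_cond, treatments=t, config=config, net=net)
    dists["no_cytokine"] = d
    conv["no_cytokine"] = ensemble_converged(ens)
    for cy in CYTOKINES:
        d, ens = simulate_condition(base_cond.with_cytokines([cy]),
                                    treatments=t, config=config, net=net)
        dists[cy] = d
        conv[cy] = ensemble_converged(ens)

    stats: dict[str, object] = {
        f"ratio_{k}": th1_treg_ratio(d) for k, d in dists.items()}

    def mixed(d: PhenotypeDistribution) -> float:
        return sum(v for lab, v in d.probs.items()
                   if {"Th1_CTL", "Treg"} <= set(lab.split("-")))

    n = config.n_trajectories
    base_r = stats["ratio_no_cytokine"]
    checks: list[tuple[str, str, str, bool]] = []
    for cy in ("IFNG", "IL12"):
        r = stats[f"ratio_{cy}"]
        up = ((r.value is None and r.th1 > TREG_EPS) or
              (not r.undefined and not base_r.undefined
               and r.value - base_r.value > 3 * math.hypot(
                   r.standard_error(), base_r.standard_error())))
        checks.append((f"{cy}: Th1/Treg ratio increases", "up",
                       f"{base_r.display()} -> {r.display()}", up))
        m = mixed(dists[cy])
        checks.append((f"{cy}: mixed Treg-Th1 category present", "present",
                       f"P={m:.4f}", m > 3 * _se(max(m, 0.01), n)))
    for ph in ("Proliferation_Survival", "Th1_CTL", "Treg"):
        delta = dists["TGFb"].marginal(ph) - dists["no_cytokine"].marginal(ph)
        tol = 3 * math.hypot(_se(dists["TGFb"].marginal(ph), n),
                             _se(dists["no_cytokine"].marginal(ph), n))
        checks.append((f"TGFb: {ph} unchanged", "no effect",
                       f"d={delta:+.4f}", abs(delta) <= tol))
    for ph in ("Th1_CTL", "Treg"):
        v = dists["IL27"].marginal(ph)
        checks.append((f"IL27 alone blocks {ph}", "P~0", f"P={v:.4f}",
                       v <= 0.01 + 3 * _se(0.01, n)))

    verdicts = [Verdict(lab, e, o, bool(ok)) for lab, e, o, ok in checks]
    return ScenarioResult("fig4_cytokines", dists, stats, verdicts, conv,
                          seed=config.seed, n_trajectories=n)


SCENARIOS = {
    "fig3_panel": single_checkpoint_panel,
    "table3_two_step": two_step_protocol,
    "table2_cd8": coexpression_panel,
    "fig4_cytokines": cytokine_panel,
}
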