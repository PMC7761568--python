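"""Gillespie simulation of the continuous-time Boolean Markov process.

Each node whose rule value disagrees with its current value carries an
exponential clock (rate = the node's activation or deactivation speed,
1 by default); the first clock to ring flips its node.  Ensembles of
trajectories are simulated in a vectorized sweep — at every step the
rule values of all trajectories are evaluated as numpy boolean arrays —
and averaged onto a uniform time grid, yielding the marginal probability
of every node and the joint distribution over the phenotype nodes
through time.  The late-time window average of the phenotype joint
distribution is the quantity the scenario protocols report (the "pie
chart" asymptotics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .exact import RateSpec
from .logic import And, BooleanNetwork, Const, LogicExpression, Not, Or, Var

__all__ = [
    "SimulationConfig",
    "InitialConditionSpec",
    "TrajectoryEnsemble",
    "PhenotypeDistribution",
    "compile_rules",
    "gillespie_trajectory",
    "simulate_ensemble",
    "asymptotic_phenotypes",
    "inhibition_strength",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ensemble simulation parameters.

    ``convergence_window`` is the trailing fraction of ``t_max`` over
    which the phenotype distribution is averaged to approximate the
    asymptotic solution; ``convergence_tol`` is the total-variation
    threshold above which the two halves of that window are considered
    discrepant (non-converged).
    """

    n_trajectories: int = 10_000
    t_max: float = 50.0
    rates: RateSpec = field(default_factory=RateSpec)
    seed: int = 0
    n_grid: int = 100
    convergence_window: float = 0.2
    convergence_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if not 0 < self.convergence_window <= 1:
            raise ValueError("convergence_window must be in (0, 1]")


@dataclass(frozen=True)
class InitialConditionSpec:
    """Initial values per node: deterministic bits and/or Bernoulli draws.

    Nodes named in neither mapping start at 0.  Input nodes keep their
    initial value for the whole trajectory because their rules are the
    identity.
    """

    values: Mapping[str, int] = field(default_factory=dict)
    random: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.values) & set(self.random)
        if overlap:
            raise ValueError(
                f"nodes specified both deterministically and randomly: {sorted(overlap)}")
        for k, p in self.random.items():
            if not 0 <= p <= 1:
                raise ValueError(f"activation probability of {k!r} must be in [0,1]")

    def sample(self, net: BooleanNetwork, n: int, rng: np.random.Generator) -> np.ndarray:
        unknown = (set(self.values) | set(self.random)) - set(net.names)
        if unknown:
            raise KeyError(f"unknown nodes in initial condition: {sorted(unknown)}")
        x = np.zeros((n, len(net)), dtype=bool)
        for nm, v in self.values.items():
            x[:, net.index[nm]] = bool(v)
        for nm, p in self.random.items():
            x[:, net.index[nm]] = rng.random(n) < p
        return x


@dataclass
class PhenotypeDistribution:
    """Probabilities over the joint states of the phenotype nodes.

    Categories are labelled by the set of phenotype nodes that are ON,
    joined with ``-`` ("Treg" means Treg ON and the other phenotypes
    OFF); the all-OFF category is labelled ``none``.
    """

    phenotype_nodes: tuple[str, ...]
    probs: dict[str, float]
    n: int  # trajectory count behind the estimate

    def marginal(self, phenotype: str) -> float:
        if phenotype not in self.phenotype_nodes:
            raise KeyError(f"unknown phenotype {phenotype!r}")
        return sum(p for label, p in self.probs.items()
                   if phenotype in label.split("-"))

    def standard_error(self, phenotype: str) -> float:
        p = self.marginal(phenotype)
        return float(np.sqrt(max(p * (1 - p), 0.0) / self.n))

    def total(self) -> float:
        return sum(self.probs.values())

    def as_dict(self) -> dict[str, float]:
        return dict(self.probs)


@dataclass
class TrajectoryEnsemble:
    """Time-gridded marginals and phenotype joint distribution."""

    net: BooleanNetwork
    config: SimulationConfig
    t_grid: np.ndarray                  # (n_grid,)
    marginals: np.ndarray               # (n_grid, n_nodes) in [0,1]
    phenotype_joint: np.ndarray         # (n_grid, 2**k) for k phenotype nodes
    phenotype_nodes: tuple[str, ...]

    def marginal(self, node: str) -> np.ndarray:
        return self.marginals[:, self.net.index[node]]

    def category_labels(self) -> list[str]:
        k = len(self.phenotype_nodes)
        labels = []
        for code in range(2 ** k):
            on = [nm for i, nm in enumerate(self.phenotype_nodes)
                  if code >> (k - 1 - i) & 1]
            labels.append("-".join(on) if on else "none")
        return labels

    def to_table(self) -> str:
        """Tab-separated time course: time, node marginals, categories."""
        header = ["time", *self.net.names, *self.category_labels()]
        rows = [header]
        for g in range(len(self.t_grid)):
            rows.append([f"{self.t_grid[g]:.6g}",
                         *(f"{v:.6f}" for v in self.marginals[g]),
                         *(f"{v:.6f}" for v in self.phenotype_joint[g])])
        return "\n".join("\t".join(r) for r in rows) + "\n"

    def summary_json(self, extra: Mapping[str, object] | None = None) -> str:
        dist = asymptotic_phenotypes(self)
        payload: dict[str, object] = {
            "seed": self.config.seed,
            "n_trajectories": self.config.n_trajectories,
            "t_max": self.config.t_max,
            "phenotype_distribution": dist.as_dict(),
            "converged": ensemble_converged(self),
        }
        if extra:
            payload.update(extra)
        return json.dumps(payload, indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# Rule compilation
# --------------------------------------------------------------------------

def _expr_source(expr: LogicExpression, index: Mapping[str, int]) -> str:
    if isinstance(expr, Var):
        return f"x[:, {index[expr.name]}]"
    if isinstance(expr, Const):
        return "ONES" if expr.value else "ZEROS"
    if isinstance(expr, Not):
        return f"~({_expr_source(expr.arg, index)})"
    if isinstance(expr, And):
        return "(" + " & ".join(_expr_source(a, index) for a in expr.args) + ")"
    if isinstance(expr, Or):
        return "(" + " | ".join(_expr_source(a, index) for a in expr.args) + ")"
    raise TypeError(f"not an expression: {expr!r}")


def compile_rules(net: BooleanNetwork) -> Callable[[np.ndarray], np.ndarray]:
    """Compile all rules into one vectorized target-value function.

    The returned function maps a boolean state matrix ``(m, n_nodes)``
    to the matrix of rule values of the same shape.
    """
    cached = getattr(net, "_compiled_targets", None)
    if cached is not None:
        return cached
    cols = [_expr_source(net.rules[nm], net.index) for nm in net.names]
    body = ", ".join(cols)
    src = ("def _targets(x):\n"
           "    ONES = np.ones(x.shape[0], dtype=bool)\n"
           "    ZEROS = np.zeros(x.shape[0], dtype=bool)\n"
           f"    return np.stack(({body},), axis=1)\n")
    ns: dict[str, object] = {"np": np}
    exec(src, ns)
    fn = ns["_targets"]
    net._compiled_targets = fn  # type: ignore[attr-defined]
    return fn  # type: ignore[return-value]


def _rate_vectors(net: BooleanNetwork, rates: RateSpec) -> tuple[np.ndarray, np.ndarray]:
    up = np.array([rates.rate(nm, 1) for nm in net.names])
    down = np.array([rates.rate(nm, 0) for nm in net.names])
    return up, down


# --------------------------------------------------------------------------
# Single-trajectory simulation (piecewise-constant path)
# --------------------------------------------------------------------------

def gillespie_trajectory(net: BooleanNetwork,
                         init: Mapping[str, int],
                         config: SimulationConfig | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """One continuous-time trajectory.

    Returns ``(jump_times, states)`` where ``states[k]`` (a bit row over
    the declared node order) holds on ``[jump_times[k], jump_times[k+1])``;
    ``jump_times[0]`` is 0.  The path ends at ``t_max`` or at absorption
    in a stable state, whichever comes first.
    """
    config = config or SimulationConfig()
    if rng is None:
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(config.seed)))
    targets = compile_rules(net)
    up, down = _rate_vectors(net, config.rates)

    x = np.array([[bool(net.state_from(init)[nm]) for nm in net.names]])
    times = [0.0]
    states = [x[0].astype(np.int8).copy()]
    t = 0.0
    while True:
        tv = targets(x)[0]
        diff = tv != x[0]
        if not diff.any():
            break
        prop = np.where(tv, up, down) * diff
        total = prop.sum()
        t += rng.exponential(1.0 / total)
        if t >= config.t_max:
            break
        u = rng.random() * total
        node = int(np.searchsorted(np.cumsum(prop), u, side="right"))
        x[0, node] = tv[node]
        times.append(t)
        states.append(x[0].astype(np.int8).copy())
    return np.array(times), np.array(states)


# --------------------------------------------------------------------------
# Vectorized ensemble simulation
# --------------------------------------------------------------------------

def simulate_ensemble(net: BooleanNetwork,
                      init_spec: InitialConditionSpec,
                      config: SimulationConfig | None = None,
                      ) -> TrajectoryEnsemble:
    """Simulate ``n_trajectories`` asynchronous paths and grid-average them.

    Deterministic for a fixed config seed.  The marginal recorded at
    grid time ``g`` is the exact value of each trajectory's
    piecewise-constant path at ``g`` (no interpolation).
    """
    config = config or SimulationConfig()
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(config.seed)))
    n_traj = config.n_trajectories
    n_nodes = len(net)
    targets = compile_rules(net)
    up, down = _rate_vectors(net, config.rates)

    pheno = tuple(net.phenotypes)
    k = len(pheno)
    pheno_idx = np.array([net.index[nm] for nm in pheno], dtype=int)
    pheno_weights = 2 ** np.arange(k - 1, -1, -1) if k else np.zeros(0, dtype=int)

    t_grid = np.linspace(0.0, config.t_max, config.n_grid)
    marg_sum = np.zeros((config.n_grid, n_nodes))
    joint_sum = np.zeros((config.n_grid, 2 ** k if k else 1))

    x = init_spec.sample(net, n_traj, rng)
    t_cur = np.zeros(n_traj)
    next_grid = np.zeros(n_traj, dtype=int)  # first unrecorded grid index
    active = np.ones(n_traj, dtype=bool)

    def record(upto: np.ndarray, mask: np.ndarray) -> None:
        """Record x for grid points in [t_cur, upto) for masked trajectories."""
        # number of grid points covered per trajectory
        hi = np.searchsorted(t_grid, upto[mask], side="left")
        lo = next_grid[mask]
        counts = np.maximum(hi - lo, 0)
        nz = counts > 0
        if nz.any():
            traj_ids = np.flatnonzero(mask)[nz]
            c = counts[nz]
            rep = np.repeat(traj_ids, c)
            starts = np.concatenate(([0], np.cumsum(c)[:-1]))
            offsets = np.arange(c.sum()) - np.repeat(starts, c)
            grid_ids = np.repeat(lo[nz], c) + offsets
            np.add.at(marg_sum, grid_ids, x[rep].astype(float))
            if k:
                codes = (x[rep][:, pheno_idx] * pheno_weights).sum(axis=1)
            else:
                codes = np.zeros(len(rep), dtype=int)
            np.add.at(joint_sum, (grid_ids, codes), 1.0)
        next_grid[mask] = np.maximum(lo, hi)

    while active.any():
        xa = x[active]
        tv = targets(xa)
        diff = tv != xa
        prop = np.where(tv, up, down) * diff
        total = prop.sum(axis=1)

        absorbed = total == 0.0
        # absorbed trajectories keep their state until t_max
        if absorbed.any():
            ids = np.flatnonzero(active)[absorbed]
            m = np.zeros(n_traj, dtype=bool)
            m[ids] = True
            record(np.full(n_traj, np.inf), m)
            active[ids] = False

        live = ~absorbed
        if not live.any():
            break
        ids = np.flatnonzero(active)  # still-active after absorption pruning
        total_live = total[live]
        dt = rng.exponential(1.0, size=len(ids)) / total_live
        t_new = t_cur[ids] + dt

        # record grid points passed during the holding interval [t_cur, t_new)
        m = np.zeros(n_traj, dtype=bool)
        m[ids] = True
        upto = np.full(n_traj, np.inf)
        upto[ids] = np.minimum(t_new, np.inf)
        record(upto, m)

        # trajectories whose next jump falls beyond t_max are done
        done = t_new >= config.t_max
        if done.any():
            active[ids[done]] = False

        go = ~done
        if go.any():
            gids = ids[go]
            p = prop[live][go]
            u = rng.random(len(gids)) * total_live[go]
            cum = np.cumsum(p, axis=1)
            node = (cum < u[:, None]).sum(axis=1)
            x[gids, node] = tv[live][go][np.arange(len(gids)), node]
            t_cur[gids] = t_new[go]

    marginals = marg_sum / n_traj
    joint = joint_sum / n_traj
    return TrajectoryEnsemble(net=net, config=config, t_grid=t_grid,
                              marginals=marginals, phenotype_joint=joint,
                              phenotype_nodes=pheno)


# --------------------------------------------------------------------------
# Asymptotics and derived statistics
# --------------------------------------------------------------------------

def _window_slices(ens: TrajectoryEnsemble) -> tuple[slice, slice, slice]:
    g0 = int(np.searchsorted(ens.t_grid,
                             ens.config.t_max * (1 - ens.config.convergence_window)))
    g0 = min(g0, len(ens.t_grid) - 2)
    mid = (g0 + len(ens.t_grid)) // 2
    return slice(g0, None), slice(g0, mid), slice(mid, None)


def ensemble_converged(ens: TrajectoryEnsemble) -> bool:
    """True when the two halves of the averaging window agree (TV distance)."""
    _, first, second = _window_slices(ens)
    d1 = ens.phenotype_joint[first].mean(axis=0)
    d2 = ens.phenotype_joint[second].mean(axis=0)
    return float(0.5 * np.abs(d1 - d2).sum()) <= ens.config.convergence_tol


def asymptotic_phenotypes(ens: TrajectoryEnsemble) -> PhenotypeDistribution:
    """Phenotype joint distribution averaged over the convergence window."""
    window, _, _ = _window_slices(ens)
    avg = ens.phenotype_joint[window].mean(axis=0)
    labels = ens.category_labels()
    probs = {lab: float(p) for lab, p in zip(labels, avg)}
    return PhenotypeDistribution(phenotype_nodes=ens.phenotype_nodes,
                                 probs=probs, n=ens.config.n_trajectories)


@dataclass(frozen=True)
class InhibitionStrength:
    """Percent loss of a phenotype probability relative to a baseline."""

    percent: float       # clipped to [0, 100] for reporting
    raw: float           # unclipped; negative = activation
    phenotype: str


def inhibition_strength(dist: PhenotypeDistribution,
                        baseline: PhenotypeDistribution,
                        phenotype: str) -> InhibitionStrength:
    """``100 * (1 - P_condition / P_baseline)`` for a phenotype marginal."""
    p_base = baseline.marginal(phenotype)
    if p_base <= 0:
        raise ZeroDivisionError(
            f"baseline probability of {phenotype!r} is zero")
    raw = 100.0 * (1.0 - dist.marginal(phenotype) / p_base)
    return InhibitionStrength(percent=float(np.clip(raw, 0.0, 100.0)),
                              raw=float(raw), phenotype=phenotype)
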