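"""Random Boolean networks and hand-built fixtures with known dynamics.

The generator exists so the dynamics engines can be exercised and
verified on networks whose behaviour is fully understood, independently
of the T-cell biology.  Two rule schemes are provided:

``inhibitory-bias``
    Rules have the form ``(a1 | a2 | ...) & !i1 & !i2 & ...`` —
    activators combined with OR, every inhibitor an AND-NOT veto.  This
    mirrors the convention of the shipped signalling model, where a
    single active inhibitor silences its target.

``random-truth-table``
    Each rule is a uniformly random Boolean function of its regulators,
    rendered in disjunctive normal form; adversarial logic with no
    monotonicity structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .logic import And, BooleanNetwork, Const, LogicExpression, NodeSpec, Not, Or, Var

__all__ = ["RandomNetworkSpec", "random_network", "fixture", "FIXTURE_NAMES"]

RULE_SCHEMES = ("inhibitory-bias", "random-truth-table")


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Parameters of a random network draw.

    ``k`` is the in-degree of every node (or a ``(lo, hi)`` inclusive
    range sampled uniformly per node); ``inhibitor_fraction`` is the
    probability that a chosen regulator acts as an inhibitor under the
    inhibitory-bias scheme.
    """

    n_nodes: int
    k: int | tuple[int, int] = 2
    inhibitor_fraction: float = 0.3
    scheme: str = "inhibitory-bias"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        lo, hi = self.k_range
        if lo < 0 or hi >= self.n_nodes and self.n_nodes > 1 and hi > self.n_nodes - 1:
            raise ValueError("in-degree must satisfy 0 <= k < n_nodes")
        if self.n_nodes == 1 and hi > 0:
            raise ValueError("a single-node network admits only k=0")
        if not 0 <= self.inhibitor_fraction <= 1:
            raise ValueError("inhibitor_fraction must be in [0, 1]")
        if self.scheme not in RULE_SCHEMES:
            raise ValueError(f"unknown rule scheme {self.scheme!r}")

    @property
    def k_range(self) -> tuple[int, int]:
        if isinstance(self.k, tuple):
            return self.k
        return (self.k, self.k)


def random_network(spec: RandomNetworkSpec) -> BooleanNetwork:
    """Draw a network; deterministic for a fixed spec (including seed)."""
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(spec.seed)))
    names = [f"n{i}" for i in range(spec.n_nodes)]
    lo, hi = spec.k_range
    nodes: list[NodeSpec] = []
    for i, nm in enumerate(names):
        k = int(rng.integers(lo, hi + 1))
        others = [x for x in names if x != nm]
        regs = sorted(rng.choice(len(others), size=k, replace=False).tolist())
        reg_names = [others[j] for j in regs]
        if k == 0:
            expr: LogicExpression = Const(int(rng.integers(0, 2)))
        elif spec.scheme == "inhibitory-bias":
            expr = _inhibitory_rule(reg_names, spec.inhibitor_fraction, rng)
        else:
            expr = _random_table_rule(reg_names, rng)
        nodes.append(NodeSpec(nm, expr))
    return BooleanNetwork(nodes)


def _inhibitory_rule(regs: list[str], inhibitor_fraction: float,
                     rng: np.random.Generator) -> LogicExpression:
    is_inhib = rng.random(len(regs)) < inhibitor_fraction
    activators = [r for r, b in zip(regs, is_inhib) if not b]
    inhibitors = [r for r, b in zip(regs, is_inhib) if b]
    parts: list[LogicExpression] = []
    if activators:
        act: LogicExpression = (Var(activators[0]) if len(activators) == 1
                                else Or([Var(a) for a in activators]))
        parts.append(act)
    else:
        parts.append(Const(1))  # pure-veto rule: ON unless inhibited
    parts.extend(Not(Var(i)) for i in inhibitors)
    return parts[0] if len(parts) == 1 else And(parts)


def _random_table_rule(regs: list[str], rng: np.random.Generator) -> LogicExpression:
    k = len(regs)
    table = rng.integers(0, 2, size=2 ** k)
    if not table.any():
        return Const(0)
    if table.all():
        return Const(1)
    minterms: list[LogicExpression] = []
    for code, bits in enumerate(itertools.product((0, 1), repeat=k)):
        if table[code]:
            lits = [Var(r) if b else Not(Var(r)) for r, b in zip(regs, bits)]
            minterms.append(lits[0] if len(lits) == 1 else And(lits))
    return minterms[0] if len(minterms) == 1 else Or(minterms)


# --------------------------------------------------------------------------
# Named fixtures with analytically known dynamics
# --------------------------------------------------------------------------

def _toggle_switch() -> BooleanNetwork:
    # mutual repression: fixed points (1,0) and (0,1)
    return BooleanNetwork([
        NodeSpec("A", Not(Var("B"))),
        NodeSpec("B", Not(Var("A"))),
    ])


def _self_activator() -> BooleanNetwork:
    # A = A: both states stable
    return BooleanNetwork([NodeSpec("A", Var("A"))])


def _oscillator_2() -> BooleanNetwork:
    # negative 2-loop A=B, B=!A: single 4-state cycle, no fixed point
    return BooleanNetwork([
        NodeSpec("A", Var("B")),
        NodeSpec("B", Not(Var("A"))),
    ])


def _chain(k: int) -> BooleanNetwork:
    # constant source relayed down a k-node cascade
    nodes = [NodeSpec("c0", Const(1))]
    nodes += [NodeSpec(f"c{i}", Var(f"c{i-1}")) for i in range(1, k)]
    return BooleanNetwork(nodes)


def _relaxation_1() -> BooleanNetwork:
    # X = 1 from X=0: P(X=1 at t) = 1 - exp(-t)
    return BooleanNetwork([NodeSpec("X", Const(1))])


_FIXTURES = {
    "toggle_switch": _toggle_switch,
    "self_activator": _self_activator,
    "oscillator_2": _oscillator_2,
    "chain_4": lambda: _chain(4),
    "relaxation_1": _relaxation_1,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str) -> BooleanNetwork:
    """A named fixture network with documented attractors and dynamics."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}") from None
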