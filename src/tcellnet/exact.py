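"""Exact analysis of asynchronous Boolean dynamics.

Asynchronous semantics: from state *s* there is one transition per node
whose rule value disagrees with its current value, and the transition
flips exactly that node.  A stable state has no outgoing transition; a
cyclic attractor is a terminal strongly connected component with at
least two states.

For small reachable state spaces the same transition structure defines a
continuous-time Markov chain (one exponential clock per discordant node,
rate = the node's activation or deactivation rate).  The transient
distribution of that chain is computed here by uniformization, with a
dense matrix-exponential cross-check available for testing; this is the
exact oracle against which the Gillespie engine is verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .logic import And, BooleanNetwork, Const, LogicExpression, Not, Or, Var, evaluate

__all__ = [
    "RateSpec",
    "Attractor",
    "async_successors",
    "fixed_points",
    "attractors",
    "reachable_states",
    "ctmc_distribution",
    "state_to_bits",
    "bits_to_state",
]

DEFAULT_EXHAUSTIVE_LIMIT = 22
DEFAULT_REACHABLE_LIMIT = 2 ** 20
CTMC_STATE_LIMIT = 4096


@dataclass(frozen=True)
class RateSpec:
    """Per-node activation (0→1) and deactivation (1→0) rates.

    All rates default to 1, the standard speed used throughout the
    shipped scenarios; overrides are keyed by node name.
    """

    up: Mapping[str, float] = field(default_factory=dict)
    down: Mapping[str, float] = field(default_factory=dict)
    default: float = 1.0

    def __post_init__(self) -> None:
        for d in (self.up, self.down):
            for k, v in d.items():
                if v <= 0:
                    raise ValueError(f"rate for {k!r} must be positive, got {v}")
        if self.default <= 0:
            raise ValueError("default rate must be positive")

    def rate(self, node: str, target_value: int) -> float:
        table = self.up if target_value == 1 else self.down
        return float(table.get(node, self.default))


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC of the asynchronous transition system."""

    kind: str  # "stable_state" | "cyclic"
    states: tuple[tuple[int, ...], ...]  # bit tuples in declared node order

    @property
    def size(self) -> int:
        return len(self.states)


def state_to_bits(net: BooleanNetwork, state: Mapping[str, int]) -> tuple[int, ...]:
    return tuple(1 if state[nm] else 0 for nm in net.names)


def bits_to_state(net: BooleanNetwork, bits: Sequence[int]) -> dict[str, int]:
    return {nm: int(b) for nm, b in zip(net.names, bits)}


def async_successors(net: BooleanNetwork, state: Mapping[str, int]
                     ) -> list[tuple[str, dict[str, int]]]:
    """All single-node-flip successors of ``state``.

    Returns ``(flipped_node, successor_state)`` pairs; empty iff the
    state is stable.
    """
    out: list[tuple[str, dict[str, int]]] = []
    for nm in net.names:
        target = evaluate(net.rules[nm], state)
        if target != state[nm]:
            succ = dict(state)
            succ[nm] = target
            out.append((nm, succ))
    return out


# --------------------------------------------------------------------------
# Fixed points: constraint propagation with branching, brute-force fallback
# --------------------------------------------------------------------------

def _partial_eval(expr: LogicExpression, assign: dict[str, int]) -> int | None:
    """Value of ``expr`` under a partial assignment, or None if undetermined."""
    if isinstance(expr, Var):
        return assign.get(expr.name)
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Not):
        v = _partial_eval(expr.arg, assign)
        return None if v is None else 1 - v
    if isinstance(expr, And):
        saw_none = False
        for a in expr.args:
            v = _partial_eval(a, assign)
            if v == 0:
                return 0
            if v is None:
                saw_none = True
        return None if saw_none else 1
    if isinstance(expr, Or):
        saw_none = False
        for a in expr.args:
            v = _partial_eval(a, assign)
            if v == 1:
                return 1
            if v is None:
                saw_none = True
        return None if saw_none else 0
    raise TypeError(f"not an expression: {expr!r}")


def fixed_points(net: BooleanNetwork,
                 clamped: Mapping[str, int] | None = None,
                 exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
                 ) -> list[dict[str, int]]:
    """All states with ``rule(s) = s``, consistent with ``clamped``.

    Uses DPLL-style search: propagate rule constraints under the current
    partial assignment, branch on the first undetermined node.  Results
    are sorted lexicographically by declared node order (0 before 1).
    The ``exhaustive_limit`` bounds the number of free (unclamped) nodes
    only as a safety net: the search never enumerates more assignments
    than the propagation tree requires.
    """
    clamped = dict(clamped or {})
    unknown = set(clamped) - set(net.names)
    if unknown:
        raise KeyError(f"clamped nodes not in network: {sorted(unknown)}")
    n_free = len(net) - len(clamped)
    if n_free > exhaustive_limit:
        raise ValueError(
            f"{n_free} free nodes exceeds the exhaustive limit {exhaustive_limit}")

    results: list[tuple[tuple[int, ...], dict[str, int]]] = []

    def propagate(assign: dict[str, int]) -> dict[str, int] | None:
        """Force values implied by rule(s)=s; None on contradiction."""
        changed = True
        while changed:
            changed = False
            for nm in net.names:
                rv = _partial_eval(net.rules[nm], assign)
                sv = assign.get(nm)
                if rv is not None:
                    if sv is None:
                        assign[nm] = rv
                        changed = True
                    elif sv != rv:
                        return None
        return assign

    def search(assign: dict[str, int]) -> None:
        assign = propagate(dict(assign))
        if assign is None:
            return
        undecided = [nm for nm in net.names if nm not in assign]
        if not undecided:
            # full assignment; propagation guarantees consistency
            results.append((state_to_bits(net, assign), assign))
            return
        nm = undecided[0]
        for v in (0, 1):
            child = dict(assign)
            child[nm] = v
            search(child)

    search(clamped)
    results.sort(key=lambda kv: kv[0])
    return [s for _, s in results]


def fixed_points_bruteforce(net: BooleanNetwork,
                            clamped: Mapping[str, int] | None = None,
                            ) -> list[dict[str, int]]:
    """Independent 2^n enumeration of fixed points (test oracle)."""
    clamped = dict(clamped or {})
    free = [nm for nm in net.names if nm not in clamped]
    out: list[dict[str, int]] = []
    for mask in range(2 ** len(free)):
        state = dict(clamped)
        for i, nm in enumerate(free):
            state[nm] = (mask >> (len(free) - 1 - i)) & 1
        if all(evaluate(net.rules[nm], state) == state[nm] for nm in net.names):
            out.append(state)
    out.sort(key=lambda s: state_to_bits(net, s))
    return out


# --------------------------------------------------------------------------
# Reachability and attractors
# --------------------------------------------------------------------------

def reachable_states(net: BooleanNetwork,
                     initial: Iterable[Mapping[str, int]],
                     limit: int = DEFAULT_REACHABLE_LIMIT,
                     ) -> tuple[list[tuple[int, ...]], list[tuple[int, int, str]]]:
    """BFS over the asynchronous transition system.

    Returns the reachable states (bit tuples, discovery order) and the
    transition list ``(from_index, to_index, flipped_node)``.
    """
    index: dict[tuple[int, ...], int] = {}
    states: list[tuple[int, ...]] = []
    edges: list[tuple[int, int, str]] = []
    frontier: list[tuple[int, ...]] = []
    for s in initial:
        bits = state_to_bits(net, net.state_from(s))
        if bits not in index:
            index[bits] = len(states)
            states.append(bits)
            frontier.append(bits)
    while frontier:
        bits = frontier.pop()
        i = index[bits]
        for node, succ in async_successors(net, bits_to_state(net, bits)):
            sb = state_to_bits(net, succ)
            j = index.get(sb)
            if j is None:
                if len(states) >= limit:
                    raise ValueError(f"reachable state space exceeds limit {limit}")
                j = index[sb] = len(states)
                states.append(sb)
                frontier.append(sb)
            edges.append((i, j, node))
    return states, edges


def attractors(net: BooleanNetwork,
               initial: Iterable[Mapping[str, int]],
               limit: int = DEFAULT_REACHABLE_LIMIT) -> list[Attractor]:
    """Terminal SCCs of the transition system reachable from ``initial``."""
    states, edges = reachable_states(net, initial, limit)
    g = nx.DiGraph()
    g.add_nodes_from(range(len(states)))
    g.add_edges_from((i, j) for i, j, _ in edges if i != j)
    out: list[Attractor] = []
    for comp in nx.strongly_connected_components(g):
        if any(j not in comp for i in comp for j in g.successors(i)):
            continue  # not terminal
        members = sorted(states[i] for i in comp)
        if len(members) == 1 and g.out_degree(next(iter(comp))) == 0:
            kind = "stable_state"
        else:
            kind = "cyclic"
        out.append(Attractor(kind=kind, states=tuple(members)))
    out.sort(key=lambda a: a.states[0])
    return out


def attractor_table(net: BooleanNetwork, atts: Sequence[Attractor]) -> str:
    """Tab-separated attractor report (id, kind, size, member bitstrings)."""
    lines = ["attractor\tkind\tsize\tstates"]
    for k, a in enumerate(atts):
        bits = ",".join("".join(map(str, s)) for s in a.states)
        lines.append(f"{k}\t{a.kind}\t{a.size}\t{bits}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Exact CTMC transient distribution (oracle for the stochastic engine)
# --------------------------------------------------------------------------

def _build_generator(net: BooleanNetwork,
                     rates: RateSpec,
                     initial: Iterable[Mapping[str, int]],
                     limit: int = CTMC_STATE_LIMIT,
                     ) -> tuple[list[tuple[int, ...]], sp.csr_matrix]:
    states, edges = reachable_states(net, initial, limit)
    n = len(states)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for i, j, node in edges:
        sb = states[j]
        target = sb[net.index[node]]
        r = rates.rate(node, target)
        rows.append(i)
        cols.append(j)
        vals.append(r)
        diag[i] -= r
    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(diag)
    q = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return states, q


def ctmc_distribution(net: BooleanNetwork,
                      rates: RateSpec | None,
                      p0: Mapping[tuple[int, ...], float] | Mapping[str, int],
                      t: float | Sequence[float],
                      limit: int = CTMC_STATE_LIMIT,
                      method: str = "uniformization",
                      tol: float = 1e-10,
                      ) -> dict[tuple[int, ...], float] | list[dict[tuple[int, ...], float]]:
    """Exact transient distribution of the asynchronous CTMC.

    ``p0`` is either a single complete state (mapping node name -> bit)
    or a distribution over bit-tuple states.  ``t`` may be a scalar or a
    sequence of times; the return mirrors that shape.  ``method`` is
    ``"uniformization"`` (default, truncation error below ``tol``) or
    ``"expm"`` (sparse matrix exponential, used as an independent
    cross-check in tests).
    """
    rates = rates or RateSpec()
    if p0 and isinstance(next(iter(p0)), str):
        init_dist = {state_to_bits(net, net.state_from(p0)): 1.0}  # type: ignore[arg-type]
    else:
        init_dist = {tuple(k): float(v) for k, v in p0.items()}  # type: ignore[union-attr]
    total = sum(init_dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"initial distribution sums to {total}, not 1")

    initial_states = [bits_to_state(net, b) for b in init_dist]
    states, q = _build_generator(net, rates, initial_states, limit)
    index = {b: i for i, b in enumerate(states)}
    p_init = np.zeros(len(states))
    for b, w in init_dist.items():
        p_init[index[b]] = w

    times = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be non-negative")

    if method == "expm":
        sols = [p_init if tt == 0 else expm_multiply(q.T.tocsc() * tt, p_init)
                for tt in times]
    elif method == "uniformization":
        sols = _uniformization(q, p_init, times, tol)
    else:
        raise ValueError(f"unknown method {method!r}")

    out = []
    for p in sols:
        p = np.clip(p, 0.0, None)
        out.append({b: float(p[i]) for i, b in enumerate(states)})
    if np.isscalar(t):
        return out[0]
    return out


_MU_SEGMENT = 32.0  # largest lam*dt handled in one uniformization pass


def _uniformization(q: sp.csr_matrix, p0: np.ndarray, times: np.ndarray,
                    tol: float) -> list[np.ndarray]:
    """Transient solution by uniformization (Jensen's method).

    Long horizons are split into segments with ``lam*dt`` bounded so the
    leading Poisson weight ``exp(-lam*dt)`` never underflows; the vector
    is propagated segment by segment.
    """
    lam = float(-q.diagonal().min())
    if lam == 0.0:  # no transitions at all: distribution is constant
        return [p0.copy() for _ in times]
    n = q.shape[0]
    # uniformized DTMC kernel: P = I + Q/lam
    p_mat = (sp.identity(n, format="csr") + q / lam).T.tocsr()

    def step(vec0: np.ndarray, dt: float, seg_tol: float) -> np.ndarray:
        mu = lam * dt
        k_max = int(mu + 8 * np.sqrt(mu) + 50)
        weight = np.exp(-mu)
        vec = vec0
        acc = weight * vec
        tail = 1.0 - weight
        k = 0
        while tail > seg_tol and k < k_max:
            k += 1
            vec = p_mat @ vec
            weight *= mu / k
            acc += weight * vec
            tail -= weight
        return acc

    order = np.argsort(times)
    out: list[np.ndarray | None] = [None] * len(times)
    t_done = 0.0
    vec = p0.copy()
    for idx in order:
        tt = float(times[idx])
        remaining = tt - t_done
        if remaining > 0:
            n_seg = max(1, int(np.ceil(lam * remaining / _MU_SEGMENT)))
            dt = remaining / n_seg
            seg_tol = tol / max(n_seg, 1)
            for _ in range(n_seg):
                vec = step(vec, dt, seg_tol)
            t_done = tt
        out[idx] = vec.copy()
    return out  # type: ignore[return-value]
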