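"""Exact dynamics: successors, fixed points, attractors, CTMC oracle."""

import numpy as np
import pytest

from tcellnet.exact import (RateSpec, async_successors, attractors,
                            bits_to_state, ctmc_distribution, fixed_points,
                            fixed_points_bruteforce, state_to_bits)
from tcellnet.logic import BooleanNetwork, NodeSpec, parse_rule
from tcellnet.synthetic import RandomNetworkSpec, fixture, random_network

from conftest import enumerate_fixed_points


class TestSuccessors:
    def test_toggle_both_rules_fire_from_origin(self, toggle):
        succ = async_successors(toggle, {"A": 0, "B": 0})
        flips = {(nm, tuple(s.values())) for nm, s in succ}
        assert flips == {("A", (1, 0)), ("B", (0, 1))}

    def test_toggle_fixed_point_has_no_successor(self, toggle):
        assert async_successors(toggle, {"A": 1, "B": 0}) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_node_rule_evaluation(self, seed):
        from tcellnet.logic import evaluate
        net = random_network(RandomNetworkSpec(n_nodes=6, k=2, seed=seed,
                                               scheme="random-truth-table"))
        rng = np.random.default_rng(seed)
        state = {nm: int(v) for nm, v in zip(net.names, rng.integers(0, 2, 6))}
        succ = dict((nm, s) for nm, s in async_successors(net, state))
        for nm in net.names:
            tv = evaluate(net.rules[nm], state)
            if tv != state[nm]:
                assert succ[nm][nm] == tv
            else:
                assert nm not in succ


class TestFixedPoints:
    def test_toggle_symmetric_bistability(self, toggle):
        assert fixed_points(toggle) == [{"A": 0, "B": 1}, {"A": 1, "B": 0}]

    def test_self_activator_both_states(self):
        net = fixture("self_activator")
        assert fixed_points(net) == [{"A": 0}, {"A": 1}]

    def test_clamping_restricts_solutions(self, toggle):
        assert fixed_points(toggle, clamped={"A": 1}) == [{"A": 1, "B": 0}]

    def test_size_limit_enforced(self):
        net = random_network(RandomNetworkSpec(n_nodes=8, k=2, seed=0))
        with pytest.raises(ValueError, match="exceeds"):
            fixed_points(net, exhaustive_limit=5)

    @pytest.mark.parametrize("scheme", ["inhibitory-bias", "random-truth-table"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, scheme, seed):
        net = random_network(RandomNetworkSpec(n_nodes=10, k=3, seed=seed,
                                               scheme=scheme))
        assert fixed_points(net) == enumerate_fixed_points(net)
        assert fixed_points(net) == fixed_points_bruteforce(net)


class TestAttractors:
    def test_toggle_two_stable_states(self, toggle):
        init = [bits_to_state(toggle, b) for b in
                [(0, 0), (0, 1), (1, 0), (1, 1)]]
        ats = attractors(toggle, init)
        assert sorted(a.kind for a in ats) == ["stable_state", "stable_state"]
        assert {a.states[0] for a in ats} == {(0, 1), (1, 0)}

    def test_oscillator_single_4_state_cycle(self):
        net = fixture("oscillator_2")
        ats = attractors(net, [{"A": 0, "B": 0}])
        assert len(ats) == 1 and ats[0].kind == "cyclic"
        assert set(ats[0].states) == {(0, 0), (0, 1), (1, 0), (1, 1)}

    @pytest.mark.parametrize("seed", range(5))
    def test_attractor_states_closed_under_successors(self, seed):
        net = random_network(RandomNetworkSpec(n_nodes=7, k=2, seed=seed,
                                               scheme="random-truth-table"))
        init = [{nm: 0 for nm in net.names}]
        for a in attractors(net, init):
            members = set(a.states)
            for bits in a.states:
                for _, succ in async_successors(net, bits_to_state(net, bits)):
                    assert state_to_bits(net, succ) in members

    def test_invariant_to_node_ordering(self):
        spec = RandomNetworkSpec(n_nodes=6, k=2, seed=4,
                                 scheme="random-truth-table")
        net = random_network(spec)
        reordered = BooleanNetwork(list(reversed(net.nodes)))
        init = {nm: 0 for nm in net.names}
        a1 = {frozenset(
            tuple(sorted(bits_to_state(net, b).items())) for b in a.states)
            for a in attractors(net, [init])}
        a2 = {frozenset(
            tuple(sorted(bits_to_state(reordered, b).items())) for b in a.states)
            for a in attractors(reordered, [init])}
        assert a1 == a2


class TestCTMC:
    def test_single_node_exponential_relaxation(self):
        """P(X=1 at t) = 1 - exp(-t) for a constant activator from 0."""
        net = fixture("relaxation_1")
        for t in (0.5, 1.0, 2.0):
            d = ctmc_distribution(net, None, {"X": 0}, t)
            assert d[(1,)] == pytest.approx(1 - np.exp(-t), abs=1e-9)

    def test_relaxation_rate_scales_time(self):
        net = fixture("relaxation_1")
        rates = RateSpec(up={"X": 2.0})
        d = ctmc_distribution(net, rates, {"X": 0}, 1.0)
        assert d[(1,)] == pytest.approx(1 - np.exp(-2.0), abs=1e-9)

    def test_toggle_symmetry_splits_evenly(self, toggle):
        p0 = {(0, 0): 1.0}
        d = ctmc_distribution(toggle, None, p0, 60.0)
        assert d[(0, 1)] == pytest.approx(0.5, abs=1e-6)
        assert d[(1, 0)] == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_uniformization_agrees_with_matrix_exponential(self, seed):
        net = random_network(RandomNetworkSpec(n_nodes=5, k=2, seed=seed,
                                               scheme="random-truth-table"))
        init = {nm: 0 for nm in net.names}
        a = ctmc_distribution(net, None, init, 2.0)
        b = ctmc_distribution(net, None, init, 2.0, method="expm")
        assert max(abs(a[k] - b[k]) for k in a) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_probability_conserved_at_all_times(self, seed):
        net = random_network(RandomNetworkSpec(n_nodes=6, k=2, seed=seed))
        init = {nm: 0 for nm in net.names}
        for d in ctmc_distribution(net, None, init, [0.5, 5.0, 50.0]):
            assert sum(d.values()) == pytest.approx(1.0, abs=1e-9)

    def test_stable_state_mass_non_decreasing(self, toggle):
        init = {(0, 0): 1.0}
        times = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
        dists = ctmc_distribution(toggle, None, init, times)
        mass = [d[(0, 1)] + d[(1, 0)] for d in dists]
        assert all(b >= a - 1e-12 for a, b in zip(mass, mass[1:]))

    def test_state_space_limit(self):
        net = random_network(RandomNetworkSpec(n_nodes=14, k=3, seed=1,
                                               scheme="random-truth-table"))
        with pytest.raises(ValueError, match="limit"):
            ctmc_distribution(net, None, {nm: 0 for nm in net.names}, 1.0,
                              limit=64)
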