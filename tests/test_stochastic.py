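"""Gillespie engine vs the exact CTMC oracle; ensemble statistics."""

import numpy as np
import pytest

from tcellnet.exact import ctmc_distribution
from tcellnet.logic import BooleanNetwork, Const, NodeSpec, parse_rule
from tcellnet.stochastic import (InitialConditionSpec, SimulationConfig,
                                 asymptotic_phenotypes, ensemble_converged,
                                 gillespie_trajectory, inhibition_strength,
                                 simulate_ensemble)
from tcellnet.synthetic import RandomNetworkSpec, fixture, random_network


def exact_marginals(net, init, t):
    d = ctmc_distribution(net, None, init, t)
    marg = np.zeros(len(net))
    for bits, p in d.items():
        marg += np.asarray(bits) * p
    return marg


class TestTrajectory:
    def test_constant_activator_single_exponential_jump(self):
        """One jump whose time is Exp(1): the empirical mean over many
        paths approaches 1."""
        net = fixture("relaxation_1")
        rng = np.random.Generator(np.random.Philox(123))
        jumps = []
        for _ in range(4000):
            times, states = gillespie_trajectory(
                net, {"X": 0}, SimulationConfig(t_max=200.0), rng=rng)
            assert len(times) == 2 and states[-1][0] == 1
            jumps.append(times[1])
        assert np.mean(jumps) == pytest.approx(1.0, abs=0.05)

    def test_stable_initial_state_never_jumps(self, toggle):
        times, states = gillespie_trajectory(toggle, {"A": 1, "B": 0},
                                             SimulationConfig(seed=0))
        assert len(times) == 1

    def test_path_is_single_flips(self):
        net = random_network(RandomNetworkSpec(n_nodes=6, k=2, seed=9,
                                               scheme="random-truth-table"))
        times, states = gillespie_trajectory(
            net, {nm: 0 for nm in net.names}, SimulationConfig(t_max=5, seed=3))
        for a, b in zip(states, states[1:]):
            assert (a != b).sum() == 1


class TestEnsemble:
    def test_same_seed_bit_identical(self, toggle):
        cfg = SimulationConfig(n_trajectories=500, t_max=5.0, seed=11)
        spec = InitialConditionSpec(random={"A": 0.5, "B": 0.5})
        e1 = simulate_ensemble(toggle, spec, cfg)
        e2 = simulate_ensemble(toggle, spec, cfg)
        assert np.array_equal(e1.marginals, e2.marginals)
        assert np.array_equal(e1.phenotype_joint, e2.phenotype_joint)

    def test_toggle_symmetry_half_half(self, toggle):
        cfg = SimulationConfig(n_trajectories=8000, t_max=30.0, seed=2)
        ens = simulate_ensemble(toggle,
                                InitialConditionSpec(random={"A": 0.5,
                                                             "B": 0.5}), cfg)
        p_a = ens.marginals[-1, toggle.index["A"]]
        se = np.sqrt(0.25 / 8000)
        assert abs(p_a - 0.5) < 3 * se

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_marginals_match_exact_ctmc(self, seed):
        net = random_network(RandomNetworkSpec(n_nodes=6, k=2, seed=seed,
                                               scheme="random-truth-table"))
        init = {nm: 0 for nm in net.names}
        cfg = SimulationConfig(n_trajectories=20_000, t_max=4.0, seed=seed + 50,
                               n_grid=101)
        ens = simulate_ensemble(net, InitialConditionSpec(values=init), cfg)
        for t in (1.0, 2.0, 3.0):
            g = int(np.argmin(np.abs(ens.t_grid - t)))
            exact = exact_marginals(net, init, ens.t_grid[g])
            se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / 20_000)
            z = (ens.marginals[g] - exact) / np.maximum(se, 1e-9)
            assert np.all(np.abs(z) < 4.0)

    def test_input_marginal_constant_at_clamped_value(self):
        net = BooleanNetwork([NodeSpec("I", parse_rule("I"), "input"),
                              NodeSpec("X", parse_rule("I"))])
        cfg = SimulationConfig(n_trajectories=200, t_max=5.0, seed=1)
        ens = simulate_ensemble(net, InitialConditionSpec(values={"I": 1,
                                                                  "X": 0}),
                                cfg)
        assert np.all(ens.marginals[:, net.index["I"]] == 1.0)

    def test_forced_node_holds_value_everywhere(self):
        net = BooleanNetwork([NodeSpec("I", parse_rule("I"), "input"),
                              NodeSpec("X", Const(0)),
                              NodeSpec("Y", parse_rule("I & !X"))])
        cfg = SimulationConfig(n_trajectories=300, t_max=5.0, seed=4)
        ens = simulate_ensemble(net, InitialConditionSpec(values={"I": 1,
                                                                  "X": 0,
                                                                  "Y": 0}),
                                cfg)
        assert np.all(ens.marginals[:, net.index["X"]] == 0.0)

    def test_standard_error_shrinks_with_sqrt_n(self):
        """Doubling the trajectory count shrinks the SE of a phenotype
        probability by ~sqrt(2) (20% tolerance), measured over repeats."""
        net = BooleanNetwork([NodeSpec("A", parse_rule("!B")),
                              NodeSpec("B", parse_rule("!A")),
                              NodeSpec("P", parse_rule("A"), "phenotype")])
        spec = InitialConditionSpec(random={"A": 0.5, "B": 0.5})

        def spread(n, seeds):
            vals = []
            for s in seeds:
                cfg = SimulationConfig(n_trajectories=n, t_max=20.0, seed=s)
                ens = simulate_ensemble(net, spec, cfg)
                vals.append(asymptotic_phenotypes(ens).marginal("P"))
            return np.std(vals)

        s_small = spread(400, range(30))
        s_big = spread(800, range(100, 130))
        assert s_small / s_big == pytest.approx(np.sqrt(2), rel=0.25)


class TestPhenotypes:
    def test_all_off_ensemble_is_all_none_category(self):
        net = BooleanNetwork([NodeSpec("I", parse_rule("I"), "input"),
                              NodeSpec("P", parse_rule("I"), "phenotype")])
        cfg = SimulationConfig(n_trajectories=100, t_max=5.0, seed=0)
        ens = simulate_ensemble(net, InitialConditionSpec(values={"I": 0,
                                                                  "P": 0}),
                                cfg)
        dist = asymptotic_phenotypes(ens)
        assert dist.probs["none"] == 1.0
        assert dist.total() == pytest.approx(1.0, abs=1e-12)

    def test_distribution_always_sums_to_one(self):
        net = random_network(RandomNetworkSpec(n_nodes=5, k=2, seed=7))
        net = BooleanNetwork([
            NodeSpec(s.name, s.rule, "phenotype" if i < 2 else s.kind)
            for i, s in enumerate(net.nodes)])
        cfg = SimulationConfig(n_trajectories=500, t_max=10.0, seed=5)
        ens = simulate_ensemble(
            net, InitialConditionSpec(values={nm: 0 for nm in net.names}), cfg)
        assert np.allclose(ens.phenotype_joint.sum(axis=1), 1.0, atol=1e-12)
        dist = asymptotic_phenotypes(ens)
        assert dist.total() == pytest.approx(1.0, abs=1e-12)

    def test_convergence_flag_detects_drift(self):
        # a very slow constant activator is still in transit at t_max
        net = BooleanNetwork([NodeSpec("P", Const(1), "phenotype")])
        from tcellnet.exact import RateSpec
        cfg = SimulationConfig(n_trajectories=3000, t_max=1.0, seed=8,
                               rates=RateSpec(up={"P": 1.0}))
        ens = simulate_ensemble(net, InitialConditionSpec(values={"P": 0}), cfg)
        assert not ensemble_converged(ens)


class TestInhibitionStrength:
    def _dist(self, p):
        from tcellnet.stochastic import PhenotypeDistribution
        return PhenotypeDistribution(("P",), {"P": p, "none": 1 - p}, 1000)

    def test_seventy_percent(self):
        s = inhibition_strength(self._dist(0.30), self._dist(1.0), "P")
        assert s.percent == pytest.approx(70.0)

    def test_identity_is_zero(self):
        s = inhibition_strength(self._dist(0.4), self._dist(0.4), "P")
        assert s.percent == pytest.approx(0.0)

    def test_activation_reported_raw_negative(self):
        s = inhibition_strength(self._dist(0.8), self._dist(0.4), "P")
        assert s.percent == 0.0 and s.raw == pytest.approx(-100.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            inhibition_strength(self._dist(0.5), self._dist(0.0), "P")
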