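"""Rule language: parsing, evaluation, round-trips, diagnostics."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from tcellnet.logic import (And, BooleanNetwork, Const, NodeSpec, Not, Or,
                            ParseError, Var, evaluate, parse_rule, regulators,
                            render, validate_network)


def brute_force_eval(expr, state):
    """Independent recursive oracle written against the AST directly."""
    if isinstance(expr, Var):
        return state[expr.name]
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Not):
        return 1 - brute_force_eval(expr.arg, state)
    if isinstance(expr, And):
        return int(all(brute_force_eval(a, state) for a in expr.args))
    return int(any(brute_force_eval(a, state) for a in expr.args))


class TestParse:
    def test_tcr_rule(self):
        """The TCR rule: antigen AND LCK/FYN AND NOT SHP."""
        e = parse_rule("Antigens & LCK_FYN & !SHP")
        assert isinstance(e, And)
        assert e.args[0] == Var("Antigens")
        assert e.args[1] == Var("LCK_FYN")
        assert e.args[2] == Not(Var("SHP"))

    def test_single_variable(self):
        assert parse_rule("A") == Var("A")

    def test_constants(self):
        assert parse_rule("0") == Const(0)
        assert parse_rule("A | 1") == Or((Var("A"), Const(1)))

    def test_precedence_not_over_and_over_or(self):
        e = parse_rule("!A & B | C")
        assert isinstance(e, Or)
        assert e.args[0] == And((Not(Var("A")), Var("B")))
        assert e.args[1] == Var("C")

    def test_de_morgan_equivalence_by_truth_table(self):
        """!(A|B) & C is logically AND(NOT A, NOT B, C): checked by
        enumerating all 8 assignments."""
        lhs = parse_rule("!(A | B) & C")
        rhs = parse_rule("!A & !B & C")
        for bits in itertools.product((0, 1), repeat=3):
            state = dict(zip("ABC", bits))
            assert evaluate(lhs, state) == evaluate(rhs, state)

    @pytest.mark.parametrize("text", ["", "  ", "A &", "& A", "(A", "A | | B",
                                      "A ? B", "!(", "A B"])
    def test_malformed_input_rejected(self, text):
        with pytest.raises(ParseError):
            parse_rule(text)

    def test_error_carries_position(self):
        with pytest.raises(ParseError) as err:
            parse_rule("A @ B")
        assert err.value.position == 2


class TestEvaluate:
    def test_tcr_activation_requires_antigen_kinase_no_phosphatase(self):
        e = parse_rule("Antigens & LCK_FYN & !SHP")
        assert evaluate(e, {"Antigens": 1, "LCK_FYN": 1, "SHP": 0}) == 1
        assert evaluate(e, {"Antigens": 1, "LCK_FYN": 1, "SHP": 1}) == 0

    def test_unassigned_variable_raises(self):
        with pytest.raises(KeyError):
            evaluate(parse_rule("A & B"), {"A": 1})

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_oracle_on_random_expressions(self, data):
        expr = data.draw(_expr_strategy())
        names = sorted(regulators(expr))
        for bits in itertools.product((0, 1), repeat=min(len(names), 10)):
            state = dict(zip(names, bits))
            if len(names) > 10:
                state.update({nm: 0 for nm in names[10:]})
            assert evaluate(expr, state) == brute_force_eval(expr, state)


def _expr_strategy(max_vars: int = 8):
    names = [f"v{i}" for i in range(max_vars)]
    leaves = st.one_of(st.sampled_from(names).map(Var),
                       st.sampled_from([0, 1]).map(Const))
    return st.recursive(
        leaves,
        lambda sub: st.one_of(
            sub.map(Not),
            st.lists(sub, min_size=2, max_size=3).map(And),
            st.lists(sub, min_size=2, max_size=3).map(Or)),
        max_leaves=12)


class TestRender:
    @given(_expr_strategy())
    @settings(max_examples=150, deadline=None)
    def test_parse_render_round_trip_preserves_truth_table(self, expr):
        back = parse_rule(render(expr))
        names = sorted(regulators(expr))
        for bits in itertools.product((0, 1), repeat=len(names)):
            state = dict(zip(names, bits))
            assert evaluate(expr, state) == evaluate(back, state)


class TestRegulators:
    def test_tcr_regulators(self):
        e = parse_rule("Antigens & LCK_FYN & !SHP")
        assert regulators(e) == {"Antigens", "LCK_FYN", "SHP"}

    def test_constant_has_none(self):
        assert regulators(Const(1)) == frozenset()

    def test_duplicates_collapse(self):
        assert regulators(parse_rule("A | A & B")) == {"A", "B"}


class TestValidate:
    def test_undeclared_regulator_reported(self):
        nodes = [NodeSpec("A", parse_rule("X"))]
        diag = validate_network(nodes)
        assert diag.undeclared_regulators == [("A", "X")]

    def test_duplicate_names_reported(self):
        nodes = [NodeSpec("PD1", Const(0)), NodeSpec("PD1", Const(1))]
        diag = validate_network(nodes)
        assert diag.duplicate_names == ["PD1"]

    def test_well_formed_network_empty_report(self):
        nodes = [NodeSpec("A", parse_rule("B"), "input"),
                 NodeSpec("B", parse_rule("A"))]
        assert not validate_network(nodes)

    def test_influence_graph_signs(self):
        net = BooleanNetwork([
            NodeSpec("A", Const(1)), NodeSpec("S", Const(0)),
            NodeSpec("T", parse_rule("A & !S"))])
        g = net.influence_graph()
        assert g.edges[("A", "T")]["sign"] == 1
        assert g.edges[("S", "T")]["sign"] == -1
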