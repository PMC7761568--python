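import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tcellnet.logic import BooleanNetwork
from tcellnet.stochastic import compile_rules
from tcellnet.synthetic import fixture
from tcellnet.tcell import build_tcell_network


@pytest.fixture(scope="session")
def tcell_net() -> BooleanNetwork:
    return build_tcell_network()


@pytest.fixture
def toggle() -> BooleanNetwork:
    return fixture("toggle_switch")


def enumerate_fixed_points(net: BooleanNetwork, clamped=None):
    """Independent fixed-point oracle: vectorized 2^n enumeration.

    Uses the compiled numpy evaluator (a different code path from both
    the recursive evaluator and the constraint-propagation search).
    """
    clamped = dict(clamped or {})
    free = [nm for nm in net.names if nm not in clamped]
    n_free = len(free)
    codes = np.arange(2 ** n_free)[:, None]
    x = np.zeros((2 ** n_free, len(net)), dtype=bool)
    for j, nm in enumerate(free):
        x[:, net.index[nm]] = (codes[:, 0] >> (n_free - 1 - j)) & 1
    for nm, v in clamped.items():
        x[:, net.index[nm]] = bool(v)
    targets = compile_rules(net)
    fixed = (targets(x) == x).all(axis=1)
    out = [{nm: int(row[net.index[nm]]) for nm in net.names}
           for row in x[fixed]]
    out.sort(key=lambda s: tuple(s[nm] for nm in net.names))
    return out


def truth_table(net: BooleanNetwork, node: str) -> tuple:
    """Truth table of one node's rule over all regulator assignments."""
    from tcellnet.logic import evaluate, regulators
    regs = sorted(regulators(net.rules[node]))
    rows = []
    for mask in range(2 ** len(regs)):
        state = {r: (mask >> (len(regs) - 1 - i)) & 1
                 for i, r in enumerate(regs)}
        rows.append(evaluate(net.rules[node], state))
    return tuple(regs), tuple(rows)
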