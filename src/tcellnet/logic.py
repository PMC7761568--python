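"""Boolean-network data model and rule language.

A logical model assigns to every node a Boolean update rule written with
the operators ``!`` (NOT), ``&`` (AND) and ``|`` (OR), e.g. ::

    TCR = Antigens & LCK_FYN & !SHP

Expressions are parsed into a small immutable AST (:class:`Var`,
:class:`Const`, :class:`Not`, :class:`And`, :class:`Or`); a
:class:`BooleanNetwork` is an ordered collection of named rules together
with the influence graph derived from them.  States are complete
``{node: 0/1}`` assignments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "LogicExpression",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "NodeSpec",
    "BooleanNetwork",
    "ParseError",
    "parse_rule",
    "render",
    "evaluate",
    "regulators",
    "validate_network",
]


# --------------------------------------------------------------------------
# Expression AST
# --------------------------------------------------------------------------

class LogicExpression:
    """Base class for rule expression nodes."""

    __slots__ = ()

    def __and__(self, other: "LogicExpression") -> "And":
        return And((self, other))

    def __or__(self, other: "LogicExpression") -> "Or":
        return Or((self, other))

    def __invert__(self) -> "Not":
        return Not(self)


@dataclass(frozen=True)
class Var(LogicExpression):
    name: str

    def __repr__(self) -> str:
        return f"Var({self.name!r})"


@dataclass(frozen=True)
class Const(LogicExpression):
    value: int  # 0 or 1

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"constant must be 0 or 1, got {self.value!r}")


@dataclass(frozen=True)
class Not(LogicExpression):
    arg: LogicExpression


@dataclass(frozen=True)
class And(LogicExpression):
    args: tuple[LogicExpression, ...]

    def __init__(self, args: Iterable[LogicExpression]):
        object.__setattr__(self, "args", tuple(args))


@dataclass(frozen=True)
class Or(LogicExpression):
    args: tuple[LogicExpression, ...]

    def __init__(self, args: Iterable[LogicExpression]):
        object.__setattr__(self, "args", tuple(args))


# --------------------------------------------------------------------------
# Parser: precedence ! > & > |, parentheses, identifiers, constants 0/1
# --------------------------------------------------------------------------

class ParseError(ValueError):
    """Malformed rule text; carries the character position of the error."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\s*(?:(?P<id>[A-Za-z_][A-Za-z0-9_]*)|(?P<const>[01])"
                       r"|(?P<op>[!&|()]))")

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            bad_pos = pos + len(text[pos:]) - len(stripped)
            raise ParseError(f"unknown token {stripped[0]!r}", bad_pos)
        if m.lastgroup == "id":
            tokens.append(("id", m.group("id"), m.start("id")))
        elif m.lastgroup == "const":
            tokens.append(("const", m.group("const"), m.start("const")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    return tokens


def parse_rule(text: str) -> LogicExpression:
    """Parse a rule string into a :class:`LogicExpression`.

    Grammar (standard precedence ``!`` > ``&`` > ``|``)::

        expr    := term ('|' term)*
        term    := factor ('&' factor)*
        factor  := '!' factor | '(' expr ')' | identifier | '0' | '1'
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty rule", 0)
    idx = 0

    def peek() -> tuple[str, str, int] | None:
        return tokens[idx] if idx < len(tokens) else None

    def advance() -> tuple[str, str, int]:
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_expr() -> LogicExpression:
        terms = [parse_term()]
        while (tok := peek()) is not None and tok[1] == "|":
            advance()
            terms.append(parse_term())
        return terms[0] if len(terms) == 1 else Or(terms)

    def parse_term() -> LogicExpression:
        factors = [parse_factor()]
        while (tok := peek()) is not None and tok[1] == "&":
            advance()
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else And(factors)

    def parse_factor() -> LogicExpression:
        tok = peek()
        if tok is None:
            raise ParseError("unexpected end of rule", len(text))
        kind, value, pos = tok
        if value == "!":
            advance()
            return Not(parse_factor())
        if value == "(":
            advance()
            inner = parse_expr()
            closing = peek()
            if closing is None or closing[1] != ")":
                raise ParseError("missing ')'", pos)
            advance()
            return inner
        if kind == "id":
            advance()
            return Var(value)
        if kind == "const":
            advance()
            return Const(int(value))
        raise ParseError(f"unexpected {value!r}", pos)

    expr = parse_expr()
    if idx != len(tokens):
        raise ParseError(f"unexpected {tokens[idx][1]!r}", tokens[idx][2])
    return expr


def render(expr: LogicExpression) -> str:
    """Render an expression back to rule text (minimal parentheses)."""

    def go(e: LogicExpression, parent_prec: int) -> str:
        if isinstance(e, Var):
            return e.name
        if isinstance(e, Const):
            return str(e.value)
        if isinstance(e, Not):
            return "!" + go(e.arg, 3)
        if isinstance(e, And):
            s = " & ".join(go(a, 2) for a in e.args)
            return f"({s})" if parent_prec > 2 else s
        if isinstance(e, Or):
            s = " | ".join(go(a, 1) for a in e.args)
            return f"({s})" if parent_prec > 1 else s
        raise TypeError(f"not an expression: {e!r}")

    return go(expr, 0)


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def evaluate(expr: LogicExpression, state: Mapping[str, int]) -> int:
    """Evaluate ``expr`` under a complete state; returns 0 or 1."""
    if isinstance(expr, Var):
        try:
            return 1 if state[expr.name] else 0
        except KeyError:
            raise KeyError(f"unassigned variable {expr.name!r}") from None
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Not):
        return 1 - evaluate(expr.arg, state)
    if isinstance(expr, And):
        for a in expr.args:
            if not evaluate(a, state):
                return 0
        return 1
    if isinstance(expr, Or):
        for a in expr.args:
            if evaluate(a, state):
                return 1
        return 0
    raise TypeError(f"not an expression: {expr!r}")


def regulators(expr: LogicExpression) -> frozenset[str]:
    """The set of variable names appearing in ``expr``."""
    if isinstance(expr, Var):
        return frozenset((expr.name,))
    if isinstance(expr, Const):
        return frozenset()
    if isinstance(expr, Not):
        return regulators(expr.arg)
    if isinstance(expr, (And, Or)):
        out: frozenset[str] = frozenset()
        for a in expr.args:
            out |= regulators(a)
        return out
    raise TypeError(f"not an expression: {expr!r}")


def _edge_signs(expr: LogicExpression, negated: bool = False,
                signs: dict[str, set[int]] | None = None) -> dict[str, set[int]]:
    """Syntactic sign of each variable occurrence: +1, -1 (both if mixed)."""
    if signs is None:
        signs = {}
    if isinstance(expr, Var):
        signs.setdefault(expr.name, set()).add(-1 if negated else +1)
    elif isinstance(expr, Not):
        _edge_signs(expr.arg, not negated, signs)
    elif isinstance(expr, (And, Or)):
        for a in expr.args:
            _edge_signs(a, negated, signs)
    return signs


# --------------------------------------------------------------------------
# Network
# --------------------------------------------------------------------------

NODE_KINDS = ("input", "internal", "phenotype")


@dataclass(frozen=True)
class NodeSpec:
    """A named node with its update rule and role annotation."""

    name: str
    rule: LogicExpression
    kind: str = "internal"

    def __post_init__(self) -> None:
        if not _IDENT_RE.match(self.name):
            raise ValueError(f"invalid node name {self.name!r}")
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")


class BooleanNetwork:
    """An ordered set of nodes with Boolean update rules.

    The node order is the declaration order; it fixes the serialization of
    states as bitstrings and the lexicographic order used by the exact
    dynamics.
    """

    def __init__(self, nodes: Sequence[NodeSpec]):
        self.nodes: tuple[NodeSpec, ...] = tuple(nodes)
        self.names: tuple[str, ...] = tuple(n.name for n in self.nodes)
        if len(set(self.names)) != len(self.names):
            seen, dups = set(), set()
            for nm in self.names:
                (dups if nm in seen else seen).add(nm)
            raise ValueError(f"duplicate node names: {sorted(dups)}")
        self.index: dict[str, int] = {nm: i for i, nm in enumerate(self.names)}
        self.rules: dict[str, LogicExpression] = {n.name: n.rule for n in self.nodes}
        self.kinds: dict[str, str] = {n.name: n.kind for n in self.nodes}

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def __iter__(self):
        return iter(self.nodes)

    def node(self, name: str) -> NodeSpec:
        return self.nodes[self.index[name]]

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.kind == "input")

    @property
    def phenotypes(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.kind == "phenotype")

    # -- derived structure -------------------------------------------------
    def influence_graph(self) -> nx.DiGraph:
        """Directed graph with an edge regulator -> target per rule variable.

        Edge attribute ``sign`` is ``+1``/``-1`` when syntactically
        determinable, ``0`` when the variable occurs under both parities.
        """
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        for spec in self.nodes:
            for src, parities in _edge_signs(spec.rule).items():
                sign = 0 if len(parities) == 2 else next(iter(parities))
                g.add_edge(src, spec.name, sign=sign)
        return g

    def replace_rules(self, new_rules: Mapping[str, LogicExpression]) -> "BooleanNetwork":
        """A copy of the network with some rules replaced."""
        unknown = set(new_rules) - set(self.names)
        if unknown:
            raise KeyError(f"unknown nodes: {sorted(unknown)}")
        return BooleanNetwork([
            NodeSpec(n.name, new_rules.get(n.name, n.rule), n.kind)
            for n in self.nodes
        ])

    def state_from(self, mapping: Mapping[str, int]) -> dict[str, int]:
        """A complete state from a mapping over all node names."""
        missing = set(self.names) - set(mapping)
        if missing:
            raise KeyError(f"state missing nodes: {sorted(missing)}")
        return {nm: 1 if mapping[nm] else 0 for nm in self.names}

    def __repr__(self) -> str:
        return f"BooleanNetwork({len(self)} nodes)"


@dataclass
class Diagnostics:
    """Validation findings; empty iff the network is well-formed."""

    undeclared_regulators: list[tuple[str, str]] = field(default_factory=list)
    duplicate_names: list[str] = field(default_factory=list)
    unreachable_phenotypes: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy when findings exist
        return bool(self.undeclared_regulators or self.duplicate_names
                    or self.unreachable_phenotypes)

    def messages(self) -> list[str]:
        out = []
        for target, reg in self.undeclared_regulators:
            out.append(f"rule of {target!r} references undeclared node {reg!r}")
        for nm in self.duplicate_names:
            out.append(f"duplicate node name {nm!r}")
        for nm in self.unreachable_phenotypes:
            out.append(f"phenotype {nm!r} is not influenced by any input")
        return out


def validate_network(net: BooleanNetwork | Sequence[NodeSpec]) -> Diagnostics:
    """Diagnostic report: undeclared regulators, duplicates, dead phenotypes.

    Accepts a raw node list so networks that would fail the
    :class:`BooleanNetwork` constructor (duplicate names) can still be
    diagnosed.
    """
    diag = Diagnostics()
    if isinstance(net, BooleanNetwork):
        nodes = net.nodes
    else:
        nodes = tuple(net)
    names = [n.name for n in nodes]
    seen: set[str] = set()
    for nm in names:
        if nm in seen and nm not in diag.duplicate_names:
            diag.duplicate_names.append(nm)
        seen.add(nm)
    declared = set(names)
    for spec in nodes:
        for reg in sorted(regulators(spec.rule)):
            if reg not in declared:
                diag.undeclared_regulators.append((spec.name, reg))
    # phenotype nodes should be downstream of at least one input
    if not diag.duplicate_names and not diag.undeclared_regulators:
        g = BooleanNetwork(nodes).influence_graph()
        inputs = {n.name for n in nodes if n.kind == "input"}
        reachable: set[str] = set()
        for src in inputs:
            reachable |= nx.descendants(g, src) | {src}
        for spec in nodes:
            if spec.kind == "phenotype" and inputs and spec.name not in reachable:
                diag.unreachable_phenotypes.append(spec.name)
    return diag
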