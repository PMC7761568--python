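"""Plain-text model and scenario-configuration I/O.

Model files use the widely understood BoolNet-style ``targets, factors``
dialect::

    targets, factors
    # kind: input
    Antigens, Antigens
    TCR, Antigens & LCK_FYN & !SHP

``#`` starts a comment; a ``# kind: <input|internal|phenotype>`` comment
immediately above a rule annotates that node's role (default:
``internal``).  Scenario configurations are YAML documents with keys
``condition`` (a named cell condition or an explicit input map),
``perturbations`` (mapping node -> forced 0/1) and ``simulation``
(fields of :class:`~tcellnet.stochastic.SimulationConfig`).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Mapping, TextIO

import yaml

from .exact import RateSpec
from .logic import (BooleanNetwork, NodeSpec, ParseError, parse_rule, render,
                    validate_network)
from .stochastic import SimulationConfig

__all__ = [
    "ModelFormatError",
    "read_model",
    "write_model",
    "model_text",
    "read_scenario_config",
]


class ModelFormatError(ValueError):
    """Malformed model file; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_model(source: str | Path | TextIO, validate: bool = True) -> BooleanNetwork:
    """Parse a BoolNet-style model file into a validated network."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_model(fh, validate=validate)

    nodes: list[NodeSpec] = []
    seen: dict[str, int] = {}
    pending_kind: str | None = None
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            pending_kind = None
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("kind:"):
                kind = body[5:].strip().lower()
                if kind not in ("input", "internal", "phenotype"):
                    raise ModelFormatError(f"unknown node kind {kind!r}", lineno)
                pending_kind = kind
            continue
        if line.lower().replace(" ", "") == "targets,factors":
            continue
        if "," not in line:
            raise ModelFormatError("expected 'target, rule'", lineno)
        target, rule_text = line.split(",", 1)
        target = target.strip()
        if target in seen:
            raise ModelFormatError(
                f"duplicate target {target!r} (first declared on line {seen[target]})",
                lineno)
        seen[target] = lineno
        # inline provenance comments after the rule
        rule_text = rule_text.split("#", 1)[0].strip()
        try:
            expr = parse_rule(rule_text)
        except ParseError as exc:
            raise ModelFormatError(f"bad rule for {target!r}: {exc}", lineno) from exc
        nodes.append(NodeSpec(target, expr, pending_kind or "internal"))
        pending_kind = None

    if not nodes:
        raise ModelFormatError("no rules found", 0)
    diag = validate_network(nodes)
    if validate and diag:
        raise ValueError("invalid model: " + "; ".join(diag.messages()))
    return BooleanNetwork(nodes)


def model_text(net: BooleanNetwork,
               header_comments: Mapping[str, str] | None = None) -> str:
    """Serialize a network in declaration order.

    ``header_comments`` maps node names to a one-line comment emitted
    above the rule (used for per-rule provenance notes).
    """
    buf = io.StringIO()
    buf.write("targets, factors\n")
    for spec in net.nodes:
        note = (header_comments or {}).get(spec.name)
        if note:
            buf.write(f"# {note}\n")
        if spec.kind != "internal":
            buf.write(f"# kind: {spec.kind}\n")
        buf.write(f"{spec.name}, {render(spec.rule)}\n")
    return buf.getvalue()


def write_model(net: BooleanNetwork, path: str | Path,
                header_comments: Mapping[str, str] | None = None) -> None:
    Path(path).write_text(model_text(net, header_comments))


# --------------------------------------------------------------------------
# Scenario configuration
# --------------------------------------------------------------------------

_SIM_KEYS = {"n_trajectories", "t_max", "seed", "n_grid",
             "convergence_window", "convergence_tol"}


def read_scenario_config(source: str | Path | TextIO, net: BooleanNetwork,
                         ) -> tuple[dict[str, int], dict[str, int], SimulationConfig]:
    """Parse a YAML scenario file against a network.

    Returns ``(condition_inputs, perturbations, simulation_config)``.
    ``condition`` may be a mapping of input-node names to 0/1;
    ``perturbations`` maps node names to forced values.  Unknown node
    names and conflicting perturbations are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_scenario_config(fh, net)
    doc = yaml.safe_load(source) or {}
    if not isinstance(doc, dict):
        raise ValueError("scenario config must be a mapping")

    cond_raw = doc.get("condition", {}) or {}
    if not isinstance(cond_raw, dict):
        raise ValueError("'condition' must map input nodes to 0/1")
    condition: dict[str, int] = {}
    for nm, v in cond_raw.items():
        if nm not in net:
            raise KeyError(f"unknown node {nm!r} in condition")
        condition[nm] = _as_bit(nm, v)

    pert_raw = doc.get("perturbations", {}) or {}
    perturbations: dict[str, int] = {}
    if isinstance(pert_raw, dict):
        items = pert_raw.items()
    elif isinstance(pert_raw, list):
        items = []
        for entry in pert_raw:
            if not (isinstance(entry, dict) and len(entry) == 1):
                raise ValueError("perturbation list entries must be single-key maps")
            items.extend(entry.items())
    else:
        raise ValueError("'perturbations' must be a mapping or list")
    for nm, v in items:
        if nm not in net:
            raise KeyError(f"unknown node {nm!r} in perturbations")
        bit = _as_bit(nm, v)
        if nm in perturbations and perturbations[nm] != bit:
            raise ValueError(f"conflicting perturbations on {nm!r}")
        perturbations[nm] = bit

    sim_raw = doc.get("simulation", {}) or {}
    unknown = set(sim_raw) - _SIM_KEYS - {"rates"}
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    kwargs = {k: sim_raw[k] for k in _SIM_KEYS if k in sim_raw}
    if "rates" in sim_raw:
        r = sim_raw["rates"] or {}
        kwargs["rates"] = RateSpec(up=r.get("up", {}), down=r.get("down", {}),
                                   default=r.get("default", 1.0))
    return condition, perturbations, SimulationConfig(**kwargs)


def _as_bit(name: str, v: object) -> int:
    if v in (0, 1, False, True):
        return int(v)  # type: ignore[arg-type]
    raise ValueError(f"value for {name!r} must be 0 or 1, got {v!r}")
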