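"""Symbolic ODE models for observability / identifiability analysis.

A model is the analytic control-affine-free system

    dx/dt = f(x, u, p),    y = g(x, p),    x(0) = x0,

with ``n`` states ``x``, ``q`` unknown parameters ``p``, ``r`` known input
functions ``u`` and ``m`` measured outputs ``y``.  ``f`` and ``g`` are
analytic expressions over the declared symbols (rational operations plus
``exp``, ``log``, ``sin``, ``cos`` and real powers, which covers Hill and
lin-log kinetics and trigonometric mechanics).  Outputs may not depend on
the inputs.

Identifiability is treated as observability of the augmented state
``x_tilde = [x, p]`` in which parameters are states with trivial dynamics
``dp/dt = 0`` (see :func:`augment`).

Models are stored as plain-text YAML documents (see :func:`load_model` /
:func:`serialize`); serialization round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import sympy as sp
import yaml
from sympy.parsing.sympy_parser import parse_expr, standard_transformations

__all__ = [
    "Model",
    "AugmentedModel",
    "AnalysisOptions",
    "ModelError",
    "load_model",
    "loads_model",
    "serialize",
    "save_model",
    "augment",
    "reparameterize",
    "parse_expression",
]


class ModelError(ValueError):
    """Raised when a model document or model operation is invalid."""


_ALLOWED_FUNCTIONS = {
    "exp": sp.exp,
    "log": sp.log,
    "sin": sp.sin,
    "cos": sp.cos,
    "sqrt": sp.sqrt,
}

_PARSE_GLOBALS = {
    "Symbol": sp.Symbol,
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
    **_ALLOWED_FUNCTIONS,
}


def parse_expression(text: str, symbols: Mapping[str, sp.Symbol]) -> sp.Expr:
    """Parse an expression string over the declared symbols.

    ``^`` is accepted as a synonym for ``**``.  Any name that is neither a
    declared symbol nor an allowed function raises :class:`ModelError`.
    """
    source = str(text).replace("^", "**")
    try:
        expr = parse_expr(
            source,
            local_dict=dict(symbols),
            global_dict=_PARSE_GLOBALS,
            transformations=standard_transformations,
            evaluate=True,
        )
    except Exception as exc:  # malformed syntax
        raise ModelError(f"cannot parse expression {text!r}: {exc}") from exc
    stray = expr.free_symbols - set(symbols.values())
    if stray:
        names = ", ".join(sorted(s.name for s in stray))
        raise ModelError(f"undeclared symbol(s) {names} in expression {text!r}")
    return expr


@dataclass(frozen=True)
class Model:
    """A declarative ODE model (states, parameters, inputs, dynamics, outputs).

    ``known`` lists symbols treated as generic fixed constants: they may
    appear in the equations but are neither states nor unknowns, so they are
    excluded from the augmented state vector.  Iterative refinement uses this
    slot for parameters already established as identifiable.
    """

    name: str
    states: tuple[sp.Symbol, ...]
    parameters: tuple[sp.Symbol, ...]
    inputs: tuple[sp.Symbol, ...]
    odes: tuple[sp.Expr, ...]
    outputs: tuple[sp.Expr, ...]
    initial_conditions: dict[sp.Symbol, object] | None = None
    known: tuple[sp.Symbol, ...] = ()

    # -- dimensions ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def q(self) -> int:
        return len(self.parameters)

    @property
    def r(self) -> int:
        return len(self.inputs)

    @property
    def m(self) -> int:
        return len(self.outputs)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ModelError("a model needs at least one state")
        if self.m < 1:
            raise ModelError("a model needs at least one output")
        if len(self.odes) != self.n:
            raise ModelError(
                f"{len(self.odes)} ODEs declared for {self.n} states"
            )
        declared: list[sp.Symbol] = [
            *self.states, *self.parameters, *self.inputs, *self.known
        ]
        seen: set[sp.Symbol] = set()
        for s in declared:
            if s in seen:
                raise ModelError(f"symbol {s} declared more than once")
            seen.add(s)
        for expr in (*self.odes, *self.outputs):
            stray = expr.free_symbols - seen
            if stray:
                names = ", ".join(sorted(x.name for x in stray))
                raise ModelError(f"undeclared symbol(s) {names} in {expr}")
        bad = [
            expr for expr in self.outputs
            if expr.free_symbols & set(self.inputs)
        ]
        if bad:
            raise ModelError(
                f"outputs may not depend on inputs: {bad[0]}"
            )
        if self.initial_conditions:
            for s in self.initial_conditions:
                if s not in set(self.states):
                    raise ModelError(f"initial condition for non-state {s}")

    # -- helpers ------------------------------------------------------
    def symbol(self, name: str) -> sp.Symbol:
        for s in (*self.states, *self.parameters, *self.inputs, *self.known):
            if s.name == name:
                return s
        raise KeyError(name)

    def with_outputs(self, outputs: Sequence[sp.Expr], name: str | None = None) -> "Model":
        return replace(
            self, outputs=tuple(outputs),
            name=name or f"{self.name}[outputs]",
        )


@dataclass(frozen=True)
class AugmentedModel:
    """A model with parameters adjoined as states with trivial dynamics.

    ``x_tilde = [x, p]`` (states first, then parameters, in declaration
    order); ``f_tilde = [f, 0, ..., 0]``.  All column indices reported by
    the rank analysis refer to this ordering.
    """

    base: Model
    x_tilde: tuple[sp.Symbol, ...]
    f_tilde: tuple[sp.Expr, ...]

    @property
    def dim(self) -> int:
        return len(self.x_tilde)

    @property
    def outputs(self) -> tuple[sp.Expr, ...]:
        return self.base.outputs


def augment(model: Model) -> AugmentedModel:
    """Adjoin the parameters to the state vector with dynamics ``dp/dt = 0``."""
    x_tilde = (*model.states, *model.parameters)
    f_tilde = (*model.odes, *(sp.Integer(0) for _ in model.parameters))
    return AugmentedModel(base=model, x_tilde=x_tilde, f_tilde=f_tilde)


@dataclass
class AnalysisOptions:
    """Tunable options for an identifiability analysis.

    max_lie_seconds
        Wall-clock budget for computing one Lie-derivative order; if an order
        takes longer, no further orders are attempted (recorded as a budget
        breach, not an error).
    max_derivatives
        Optional hard cap on the Lie-derivative order.
    rank_mode
        ``"numeric"`` evaluates the observability-identifiability matrix
        exactly at random prime-valued points (fast, generic w.h.p.);
        ``"symbolic"`` computes the exact generic rank (small models only).
    numeric_domain
        Arithmetic for the numeric evaluation: ``"gf"`` (exact arithmetic
        in a random prime field per trial; fast) or ``"rational"`` (exact
        rational arithmetic).  Both are specialisations that can only
        lower the generic rank, guarded by the multi-trial maximum.
    numeric_trials
        Number of independent random prime assignments; the maximum rank over
        trials is reported, which guards against accidental cancellations.
    decompose_policy
        ``"never"``, ``"on_budget_breach"`` or ``"always"``.
    submodels
        Optional explicit list of state subsets (bypasses the optimization).
    use_known_ic
        Evaluate the matrix at the model's initial conditions instead of a
        generic point (detects loss of identifiability from special starts).
    input_derivative_order
        Number of nonzero time-derivatives assumed for the inputs (0 =
        constant-input Lie derivatives).
    """

    max_lie_seconds: float = 100.0
    max_derivatives: int | None = None
    rank_mode: str = "numeric"
    numeric_domain: str = "gf"
    numeric_trials: int = 3
    seed: int = 0
    decompose_policy: str = "on_budget_breach"
    submodels: list[list[str]] | None = None
    max_states_per_submodel: int = 3
    use_known_ic: bool = False
    input_derivative_order: int = 0
    find_combinations: bool = True
    vns_shakes: int = 40
    max_refinement_rounds: int = 4

    def __post_init__(self) -> None:
        if self.numeric_trials < 1:
            raise ModelError("numeric_trials must be >= 1")
        if self.rank_mode not in ("symbolic", "numeric"):
            raise ModelError(f"unknown rank_mode {self.rank_mode!r}")
        if self.numeric_domain not in ("gf", "rational"):
            raise ModelError(f"unknown numeric_domain {self.numeric_domain!r}")
        if self.decompose_policy not in ("never", "on_budget_breach", "always"):
            raise ModelError(
                f"unknown decompose_policy {self.decompose_policy!r}"
            )
        if self.max_lie_seconds <= 0:
            raise ModelError("max_lie_seconds must be positive")
        if self.input_derivative_order < 0:
            raise ModelError("input_derivative_order must be >= 0")


# ---------------------------------------------------------------------------
# Document format
# ---------------------------------------------------------------------------

def loads_model(document: str) -> Model:
    """Parse a model-definition document (YAML text)."""
    try:
        raw = yaml.safe_load(document)
    except yaml.YAMLError as exc:
        raise ModelError(f"invalid model document: {exc}") from exc
    if not isinstance(raw, dict):
        raise ModelError("model document must be a mapping")
    for key in ("name", "states", "odes", "outputs"):
        if key not in raw:
            raise ModelError(f"model document missing field {key!r}")

    def _symbols(names: Iterable[str]) -> tuple[sp.Symbol, ...]:
        out = []
        for nm in names or []:
            if not isinstance(nm, str) or not nm.isidentifier():
                raise ModelError(f"invalid symbol name {nm!r}")
            out.append(sp.Symbol(nm))
        return tuple(out)

    states = _symbols(raw["states"])
    parameters = _symbols(raw.get("parameters", []))
    inputs = _symbols(raw.get("inputs", []))
    known = _symbols(raw.get("known", []))
    table = {s.name: s for s in (*states, *parameters, *inputs, *known)}
    if len(table) != len(states) + len(parameters) + len(inputs) + len(known):
        raise ModelError(
            "symbol declared more than once across states/parameters/inputs"
        )

    odes = tuple(parse_expression(e, table) for e in raw["odes"])
    out_table = {k: v for k, v in table.items()}
    outputs = tuple(parse_expression(e, out_table) for e in raw["outputs"])

    x0 = None
    if raw.get("initial_conditions"):
        x0 = {}
        for nm, val in raw["initial_conditions"].items():
            if nm not in table:
                raise ModelError(f"initial condition for undeclared symbol {nm}")
            x0[table[nm]] = (
                val if isinstance(val, (int, float))
                else parse_expression(str(val), table)
            )
    return Model(
        name=str(raw["name"]), states=states, parameters=parameters,
        inputs=inputs, odes=odes, outputs=outputs,
        initial_conditions=x0, known=known,
    )


def load_model(path) -> Model:
    """Load a model-definition document from a file path."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_model(fh.read())


def _expr_str(expr: sp.Expr) -> str:
    return sp.sstr(expr).replace("**", "^")


def serialize(model: Model) -> str:
    """Serialize a model to its document form (round-trips exactly)."""
    doc: dict = {
        "name": model.name,
        "states": [s.name for s in model.states],
        "parameters": [s.name for s in model.parameters],
        "inputs": [s.name for s in model.inputs],
        "odes": [_expr_str(e) for e in model.odes],
        "outputs": [_expr_str(e) for e in model.outputs],
    }
    if model.known:
        doc["known"] = [s.name for s in model.known]
    if model.initial_conditions:
        doc["initial_conditions"] = {
            s.name: (v if isinstance(v, (int, float)) else _expr_str(v))
            for s, v in model.initial_conditions.items()
        }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


def save_model(model: Model, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize(model))


# ---------------------------------------------------------------------------
# Reparameterization
# ---------------------------------------------------------------------------

def reparameterize(
    model: Model,
    fix: Mapping[sp.Symbol | str, object] | None = None,
    substitute: Mapping[tuple, tuple] | None = None,
) -> Model:
    """Fix parameters and/or collapse parameter groups into combinations.

    ``fix`` maps parameters to numeric values (the parameter becomes a plain
    constant) or to ``None`` (the parameter is kept symbolic but moved to the
    ``known`` set, i.e. treated as a known constant of generic value).

    ``substitute`` maps a tuple of old parameters to ``(new_symbol, expr)``
    where ``expr`` defines the combination in terms of the old parameters,
    e.g. ``{(th17, th22): (Phi, th17*th22)}``.  The old parameters must occur
    in the model only through that combination; otherwise the substitution is
    rejected.
    """
    fix = dict(fix or {})
    substitute = dict(substitute or {})

    def _sym(s):
        return model.symbol(s) if isinstance(s, str) else s

    params = list(model.parameters)
    odes = list(model.odes)
    outputs = list(model.outputs)
    known = list(model.known)

    for p, value in list(fix.items()):
        p = _sym(p)
        if p not in params:
            raise ModelError(f"cannot fix non-parameter {p}")
        params.remove(p)
        if value is None:
            known.append(p)
        else:
            val = sp.nsimplify(value, rational=True)
            odes = [e.subs(p, val) for e in odes]
            outputs = [e.subs(p, val) for e in outputs]

    for group, (new_sym, expr) in substitute.items():
        group = tuple(_sym(s) for s in group)
        new_sym = sp.Symbol(new_sym) if isinstance(new_sym, str) else new_sym
        if isinstance(expr, str):
            expr = parse_expression(expr, {s.name: s for s in group})
        missing = [s for s in group if s not in params]
        if missing:
            raise ModelError(f"cannot substitute non-parameter {missing[0]}")
        if set(expr.free_symbols) - set(group):
            raise ModelError(
                "combination expression may involve only the replaced parameters"
            )
        # Solve the defining relation for one member and eliminate it.
        pivot = None
        sols = None
        for cand in group:
            sols = sp.solve(sp.Eq(expr, new_sym), cand)
            if len(sols) == 1:
                pivot = cand
                break
        if pivot is None:
            raise ModelError(f"cannot solve {expr} = {new_sym} for a member")
        rewritten_odes = [sp.cancel(e.subs(pivot, sols[0])) for e in odes]
        rewritten_outs = [sp.cancel(e.subs(pivot, sols[0])) for e in outputs]
        leftover = set()
        for e in (*rewritten_odes, *rewritten_outs):
            leftover |= e.free_symbols & (set(group) - {pivot})
        if leftover:
            raise ModelError(
                f"parameters {sorted(s.name for s in leftover)} occur outside "
                f"the combination {expr}; substitution invalid"
            )
        odes, outputs = rewritten_odes, rewritten_outs
        idx = min(params.index(s) for s in group)
        for s in group:
            params.remove(s)
        params.insert(idx, new_sym)

    return Model(
        name=model.name, states=model.states, parameters=tuple(params),
        inputs=model.inputs, odes=tuple(odes), outputs=tuple(outputs),
        initial_conditions=model.initial_conditions, known=tuple(known),
    )
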