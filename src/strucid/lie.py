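"""Lie derivatives, the observability-identifiability matrix, and its rank.

The information content of the output time-derivatives is generated by
iterated Lie derivatives of the output map ``g`` along the (augmented)
vector field ``f_tilde``:

    L^0 g = g,      L^{i} g = (d L^{i-1} g / d x_tilde) . f_tilde

Stacking the Jacobians of ``L^0 g .. L^k g`` with respect to
``x_tilde = [x, p]`` gives the observability-identifiability matrix
``OI``.  If ``rank(OI) = n + q`` at a generic point, the model is locally
observable and its parameters locally structurally identifiable (the
observability rank condition, applied to the augmented system).  The rank
statement is local: a system can satisfy it and still be globally
indistinguishable from a distant twin (e.g. angle measurements through
sin/cos), so no global claims are made here.

The smallest order at which full rank is possible is
``n_d = ceil((n+q)/m - 1)`` and orders beyond ``n + q - 1`` can never
increase the rank, which brackets the recursion; within the bracket the
build stops as soon as the rank stalls.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from fractions import Fraction

import sympy as sp

from .model import AnalysisOptions, AugmentedModel, Model, augment
from .series import (
    DegeneratePointError,
    Domain,
    EvaluationPoint,
    exponent_symbols,
    matrix_rank_rows,
    oi_blocks_at_point,
    random_point,
    rational_rank,
    rank_without_columns,
)

__all__ = [
    "compute_nd",
    "lie_derivative",
    "input_derivative_symbol",
    "OIMatrix",
    "RankResult",
    "build_oi",
    "matrix_rank",
    "oic_test",
]


def compute_nd(n: int, q: int, m: int) -> int:
    """Minimum Lie-derivative order at which OI can reach full rank.

    ``ceil((n+q)/m - 1)``, floored at zero.
    """
    if n < 1 or m < 1 or q < 0:
        raise ValueError("need n >= 1, m >= 1, q >= 0")
    return max(0, -((n + q) // -m) - 1)


def input_derivative_symbol(u: sp.Symbol, order: int) -> sp.Symbol:
    """Symbol standing for the ``order``-th time derivative of input ``u``."""
    if order == 0:
        return u
    return sp.Symbol(u.name + "'" * order)


def _extended_field(aug: AugmentedModel, input_order: int):
    """Variables and dynamics including input-derivative chains.

    In constant-input mode the inputs are plain symbols with zero time
    derivative.  With ``input_order = d > 0`` the inputs are analytic time
    functions: symbols u, u', .., u^(d) are chained (du^(j)/dt = u^(j+1),
    du^(d)/dt = 0), which is how the chain rule enters the Lie recursion.
    """
    variables = list(aug.x_tilde)
    dynamics = list(aug.f_tilde)
    for u in aug.base.inputs:
        for j in range(input_order):
            variables.append(input_derivative_symbol(u, j))
            dynamics.append(input_derivative_symbol(u, j + 1))
        if input_order > 0:
            variables.append(input_derivative_symbol(u, input_order))
            dynamics.append(sp.Integer(0))
    return variables, dynamics


def lie_derivative(
    aug: AugmentedModel, order: int, input_derivative_order: int = 0
) -> list[sp.Expr]:
    """The ``order``-th Lie derivative of the outputs along ``f_tilde``.

    Order 0 returns ``g`` itself.  Inputs are held symbolic; with
    ``input_derivative_order > 0`` their time derivatives up to that order
    appear as primed symbols (derivatives beyond it are zero).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    variables, dynamics = _extended_field(aug, input_derivative_order)
    cur = sp.Matrix(list(aug.outputs))
    fvec = sp.Matrix(dynamics)
    for _ in range(order):
        cur = cur.jacobian(variables) * fvec
    return list(cur)


# ---------------------------------------------------------------------------
# OI matrix
# ---------------------------------------------------------------------------

# expression-size threshold above which per-order simplification is skipped
_SIMPLIFY_NODE_LIMIT = 2000


@dataclass
class _Trial:
    """One prime-valued evaluation of the OI matrix (numeric mode)."""

    point: EvaluationPoint
    rows: list[list] = field(default_factory=list)
    input_series: dict | None = None
    domain: Domain | None = None


@dataclass
class OIMatrix:
    """The (possibly partially built) observability-identifiability matrix.

    ``blocks`` holds the symbolic m x (n+q) Jacobian blocks when built in
    symbolic mode.  In numeric mode the blocks exist only as exact rational
    evaluations at the trial points (``trials``); block ``i`` of trial ``t``
    occupies rows ``i*m .. (i+1)*m - 1`` of ``trials[t].rows``.
    """

    model: AugmentedModel
    mode: str
    columns: tuple[sp.Symbol, ...]
    blocks: list[sp.Matrix] = field(default_factory=list)
    trials: list[_Trial] = field(default_factory=list)
    order_built: int = -1
    rank_history: dict[int, int] = field(default_factory=dict)
    evaluation_point: dict | None = None
    stop_reason: str | None = None
    order_log: list[tuple] = field(default_factory=list)
    input_derivative_order: int = 0
    opts: AnalysisOptions | None = None

    @property
    def m(self) -> int:
        return len(self.model.outputs)

    @property
    def n_rows(self) -> int:
        return self.m * (self.order_built + 1)

    @property
    def full_rank_needed(self) -> int:
        return len(self.columns)

    def stacked(self) -> sp.Matrix:
        if self.mode != "symbolic":
            raise ValueError("symbolic blocks not built (numeric mode)")
        return sp.Matrix.vstack(*self.blocks)

    @property
    def complete(self) -> bool:
        """True when adding further derivatives provably cannot help."""
        return self.stop_reason in ("full_rank", "rank_stalled", "max_order")

    @property
    def rank_rising_at_stop(self) -> bool:
        if self.complete:
            return False
        orders = sorted(self.rank_history)
        if len(orders) < 2:
            return True
        return self.rank_history[orders[-1]] > self.rank_history[orders[-2]]

    # -- ranks --------------------------------------------------------
    def rank(self) -> int:
        orders = sorted(self.rank_history)
        if orders:
            return self.rank_history[orders[-1]]
        return matrix_rank(self)

    def rank_without(self, column) -> int:
        """Rank after deleting one column (symbol or index)."""
        j = (
            column
            if isinstance(column, int)
            else list(self.columns).index(column)
        )
        if self.mode == "numeric":
            return max(
                rank_without_columns(t.rows, {j}) for t in self.trials
            )
        mat = self.stacked()
        keep = [c for c in range(mat.cols) if c != j]
        return _symbolic_rank(mat[:, keep])


@dataclass
class RankResult:
    """Outcome of the observability-identifiability rank test."""

    rank: int
    full_rank_needed: int
    orders_used: int
    mode: str
    trials: int
    verdict: str
    oi: OIMatrix | None = None

    @property
    def identifiable(self) -> bool:
        return self.verdict == "observable_and_identifiable"


def _symbolic_rank(mat: sp.Matrix) -> int:
    return mat.rank(simplify=lambda e: sp.cancel(sp.together(e)))


def _numeric_rank_of_symbolic(
    mat: sp.Matrix, symbols, trials: int, seed: int
) -> int:
    """Prime-substitution rank of a symbolic matrix (max over trials)."""
    best = 0
    small = exponent_symbols(list(mat))
    for t in range(trials):
        point = random_point(list(symbols), seed + 1000003 * t, small=small)
        subs = {s: sp.Rational(v) for s, v in point.assignment.items()}
        rows = []
        for i in range(mat.rows):
            row = []
            for j in range(mat.cols):
                val = mat[i, j].xreplace(subs)
                val = sp.nsimplify(val, rational=True) if not val.is_Rational else val
                if not val.is_Rational:
                    val = sp.Rational(sp.N(val, 50))
                row.append(Fraction(int(val.p), int(val.q)))
            rows.append(row)
        best = max(best, rational_rank(rows))
    return best


def matrix_rank(
    oi: OIMatrix,
    mode: str | None = None,
    trials: int | None = None,
    seed: int | None = None,
) -> int:
    """Rank of the built OI matrix.

    Symbolic mode computes the exact generic rank.  Numeric mode evaluates
    the matrix with every distinct symbol replaced by a distinct prime
    (random assignment per trial, exact rational arithmetic) and returns the
    maximum rank over trials — specialisation can only lower a generic rank,
    never raise it, so the maximum is the best lower bound and equals the
    generic rank with overwhelming probability.
    """
    opts = oi.opts or AnalysisOptions()
    mode = mode or opts.rank_mode
    trials = trials or opts.numeric_trials
    seed = opts.seed if seed is None else seed
    if oi.mode == "numeric":
        if mode == "symbolic":
            raise ValueError("numeric OI evaluation cannot yield a symbolic rank")
        return max(matrix_rank_rows(t.rows) for t in oi.trials)
    mat = oi.stacked()
    if mode == "symbolic":
        return _symbolic_rank(mat)
    symbols = set().union(*(set(b.free_symbols) for b in oi.blocks)) or set()
    return _numeric_rank_of_symbolic(mat, sorted(symbols, key=lambda s: s.name),
                                     trials, seed)


# ---------------------------------------------------------------------------
# Recursive build with early stopping
# ---------------------------------------------------------------------------

def _light_simplify(expr: sp.Expr) -> sp.Expr:
    if sp.count_ops(expr) > _SIMPLIFY_NODE_LIMIT:
        return expr
    return sp.cancel(sp.together(expr))


def build_oi(aug: AugmentedModel, opts: AnalysisOptions | None = None) -> OIMatrix:
    """Build the OI matrix recursively with early stopping.

    Blocks are added starting at order 0.  From order ``n_d`` onward the
    rank is computed after each added block; the build stops when the rank
    reaches ``n + q`` (full), when an added order does not increase the rank
    (it can then never increase again), at order ``n + q - 1`` (the proven
    cap), or when one order exceeds the per-derivative time budget.  A
    budget breach is a recorded stop reason, not an error: partial matrices
    still support partial analyses.
    """
    opts = opts or AnalysisOptions()
    model = aug.base
    n_cols = aug.dim
    nd = compute_nd(model.n, model.q, model.m)
    cap = n_cols - 1
    if opts.max_derivatives is not None:
        cap = min(cap, opts.max_derivatives)

    oi = OIMatrix(
        model=aug,
        mode=opts.rank_mode,
        columns=tuple(aug.x_tilde),
        input_derivative_order=opts.input_derivative_order,
        opts=opts,
    )

    if opts.rank_mode == "numeric":
        _build_numeric(oi, aug, opts, nd, cap)
    else:
        _build_symbolic(oi, aug, opts, nd, cap)
    return oi


def _stop_checks(oi: OIMatrix, order: int, rank: int, nd: int, cap: int) -> bool:
    prev = oi.rank_history.get(order - 1)
    oi.rank_history[order] = rank
    if rank == oi.full_rank_needed:
        oi.stop_reason = "full_rank"
        return True
    if prev is not None and rank <= prev:
        oi.stop_reason = "rank_stalled"
        return True
    if order >= cap:
        oi.stop_reason = (
            "max_order" if cap == len(oi.columns) - 1 else "max_derivatives"
        )
        return True
    return False


def _trial_points(aug: AugmentedModel, opts: AnalysisOptions):
    """Evaluation points for the numeric trials (honouring known ICs)."""
    base = aug.base
    symbols = [
        *aug.x_tilde, *base.inputs, *base.known,
    ]
    fixed = {}
    if opts.use_known_ic and base.initial_conditions:
        for s, v in base.initial_conditions.items():
            if isinstance(v, (int, float)):
                fixed[s] = v
            elif getattr(v, "is_number", False):
                fixed[s] = v
    small = exponent_symbols([*base.odes, *base.outputs])
    points = []
    for t in range(opts.numeric_trials):
        points.append(
            random_point(symbols, opts.seed + 7919 * t, fixed=fixed,
                         small=small)
        )
    return points


def _make_trials(aug, opts, seed_shift=0):
    base = aug.base
    small = exponent_symbols([*base.odes, *base.outputs])
    points = _trial_points(aug, opts) if seed_shift == 0 else [
        random_point(
            [*aug.x_tilde, *base.inputs, *base.known],
            opts.seed + seed_shift + 7919 * i,
            small=small,
        )
        for i in range(opts.numeric_trials)
    ]
    trials = []
    for p in points:
        iser = None
        if opts.input_derivative_order > 0:
            iser = {}
            for u in base.inputs:
                vals = [p.assignment[u]]
                for _ in range(opts.input_derivative_order):
                    vals.append(Fraction(p._rng.randrange(2, 500)))
                iser[u] = vals
        domain = (
            Domain() if opts.numeric_domain == "rational"
            else Domain.random_field(p._rng)
        )
        trials.append(_Trial(point=p, input_series=iser, domain=domain))
    return trials


def _build_numeric(oi, aug, opts, nd, cap):
    base = aug.base
    trials = _make_trials(aug, opts)
    oi.trials = trials
    if opts.use_known_ic and base.initial_conditions:
        oi.evaluation_point = dict(base.initial_conditions)
    order = -1
    retries = 0
    while order < cap:
        target = min(max(nd, order + 1), cap)
        t0 = time.perf_counter()
        try:
            for t in trials:
                blocks = oi_blocks_at_point(
                    states=list(base.states),
                    columns=list(oi.columns),
                    odes=list(base.odes),
                    outputs=list(base.outputs),
                    point=t.point,
                    n_orders=target,
                    extra_symbols=[*base.inputs, *base.known],
                    input_series=t.input_series,
                    domain=t.domain,
                )
                t.rows = [row for b in blocks for row in b]
        except DegeneratePointError:
            if opts.use_known_ic or retries >= 5:
                raise
            retries += 1
            trials = _make_trials(aug, opts, seed_shift=104729 * retries)
            oi.trials = trials
            continue
        order = target
        oi.order_built = order
        elapsed = time.perf_counter() - t0
        rank = max(matrix_rank_rows(t.rows) for t in trials)
        oi.order_log.append((order, oi.n_rows, rank, elapsed))
        if _stop_checks(oi, order, rank, nd, cap):
            break
        if elapsed > opts.max_lie_seconds:
            oi.stop_reason = "budget"
            break
    if oi.stop_reason is None:
        oi.stop_reason = (
            "max_order" if order >= len(oi.columns) - 1 else "max_derivatives"
        )


def _build_symbolic(oi, aug, opts, nd, cap):
    variables, dynamics = _extended_field(aug, opts.input_derivative_order)
    fvec = sp.Matrix(dynamics)
    cur = sp.Matrix(list(aug.outputs))
    order = 0
    t0 = time.perf_counter()
    block = cur.jacobian(list(oi.columns))
    oi.blocks.append(block)
    oi.order_built = 0
    elapsed = time.perf_counter() - t0
    oi.order_log.append((0, oi.m, None, elapsed))
    while True:
        if order >= nd:
            rank = matrix_rank(oi)
            oi.order_log[-1] = (*oi.order_log[-1][:2], rank, oi.order_log[-1][3])
            if _stop_checks(oi, order, rank, nd, cap):
                return
        if order >= cap:
            oi.stop_reason = (
                "max_order" if cap == len(oi.columns) - 1 else "max_derivatives"
            )
            return
        if elapsed > opts.max_lie_seconds:
            oi.stop_reason = "budget"
            if order < nd:
                rank = matrix_rank(oi)
                oi.rank_history[order] = rank
                oi.order_log[-1] = (*oi.order_log[-1][:2], rank, oi.order_log[-1][3])
            return
        t0 = time.perf_counter()
        ext = cur.jacobian(variables) * fvec
        cur = ext.applyfunc(_light_simplify)
        oi.blocks.append(cur.jacobian(list(oi.columns)))
        order += 1
        oi.order_built = order
        elapsed = time.perf_counter() - t0
        oi.order_log.append((order, oi.m * (order + 1), None, elapsed))


def symbolic_blocks(
    aug: AugmentedModel,
    orders: int,
    input_derivative_order: int = 0,
    opts: AnalysisOptions | None = None,
) -> OIMatrix:
    """Build the symbolic OI blocks up to a prescribed order, no rank checks.

    Used when the symbolic matrix itself is needed (null-space /
    combination search) but the stopping order is already known from a
    numeric analysis, so no expensive symbolic ranks are computed.
    """
    variables, dynamics = _extended_field(aug, input_derivative_order)
    fvec = sp.Matrix(dynamics)
    cur = sp.Matrix(list(aug.outputs))
    oi = OIMatrix(
        model=aug, mode="symbolic", columns=tuple(aug.x_tilde),
        input_derivative_order=input_derivative_order,
        opts=opts or AnalysisOptions(rank_mode="symbolic"),
    )
    oi.blocks.append(cur.jacobian(list(oi.columns)))
    for order in range(1, orders + 1):
        cur = (cur.jacobian(variables) * fvec).applyfunc(_light_simplify)
        oi.blocks.append(cur.jacobian(list(oi.columns)))
    oi.order_built = orders
    oi.stop_reason = "max_derivatives"
    return oi


# ---------------------------------------------------------------------------

def oic_test(model: Model, opts: AnalysisOptions | None = None) -> RankResult:
    """Observability-identifiability condition: is rank(OI) = n + q?

    With ``opts.use_known_ic`` the matrix is evaluated at the supplied
    initial conditions instead of a generic point, which can expose
    identifiability losses at special starts.
    """
    opts = opts or AnalysisOptions()
    aug = augment(model)
    oi = build_oi(aug, opts)
    rank = oi.rank()
    verdict = (
        "observable_and_identifiable"
        if rank == aug.dim
        else "rank_deficient"
    )
    return RankResult(
        rank=rank,
        full_rank_needed=aug.dim,
        orders_used=oi.order_built,
        mode=opts.rank_mode,
        trials=opts.numeric_trials if opts.rank_mode == "numeric" else 1,
        verdict=verdict,
        oi=oi,
    )
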