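"""Identifiable combinations of unidentifiable parameters.

When the OI matrix is rank deficient, the columns of the identifiable
parameters are removed, leaving the reduced matrix ``O_U``.  A vector
``v`` in the right null space of ``O_U`` generates the first-order PDE

    sum_i v_i dPhi/dp_i = 0,

whose first integrals ``Phi(p)`` are functions of the unidentifiable
parameters that the outputs *can* determine — identifiable combinations.
Solving the PDE by characteristics is feasible for the coefficient
patterns that occur in practice: constant coefficients give linear
combinations (``[1, -1] -> p1 + p2``) and monomial-ratio coefficients give
products, ratios and powers (``[-p_i/p_j, 1] -> p_i * p_j``).  Anything
else is returned as the unsolved PDE, which is still informative.

Null vectors whose support involves state columns describe symmetries that
mix states and parameters; they are reported but not solved for parameter
combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy as sp

from .classify import UNIDENTIFIABLE, Classification
from .lie import OIMatrix
from .series import random_point, rational_rank

__all__ = [
    "ReducedMatrix",
    "KernelVector",
    "Combination",
    "reduce_to_unidentifiable",
    "kernel_basis",
    "solve_combination",
    "find_combinations",
]


@dataclass
class ReducedMatrix:
    """``O_U``: the OI columns of the unidentifiable elements."""

    matrix: sp.Matrix
    columns: tuple[sp.Symbol, ...]
    parameters: tuple[sp.Symbol, ...]   # which columns are parameters


@dataclass
class KernelVector:
    """A right null-space vector of ``O_U``, indexed by its columns."""

    coefficients: tuple[sp.Expr, ...]
    columns: tuple[sp.Symbol, ...]

    @property
    def support(self) -> tuple[sp.Symbol, ...]:
        return tuple(
            s for s, c in zip(self.columns, self.coefficients) if c != 0
        )

    def parameters_only(self, parameters) -> bool:
        pset = set(parameters)
        return all(s in pset for s in self.support)


@dataclass
class Combination:
    """An identifiable combination, or the PDE defining it when unsolved."""

    expression: sp.Expr | None
    solved: bool
    pde: sp.Expr
    vector: KernelVector
    kind: str = "combination"   # 'combination' | 'symmetry'


def reduce_to_unidentifiable(
    oi: OIMatrix,
    classification: Classification,
    include_states: bool = False,
) -> ReducedMatrix:
    """Remove the columns of identifiable elements, keeping ``O_U``.

    Requires the OI matrix to have been built symbolically: the null space
    is a symbolic object.  By default only unidentifiable *parameter*
    columns are retained; ``include_states`` keeps unobservable-state
    columns too (their null vectors describe state-parameter symmetries).
    """
    params = set(oi.model.base.parameters)
    keep = []
    for j, s in enumerate(oi.columns):
        if classification.rank_verdicts.get(s) != UNIDENTIFIABLE:
            continue
        if s in params or include_states:
            keep.append(j)
    if not keep:
        raise ValueError(
            "no unidentifiable elements: the model is already identifiable"
        )
    mat = oi.stacked()
    cols = tuple(oi.columns[j] for j in keep)
    return ReducedMatrix(
        matrix=mat[:, keep],
        columns=cols,
        parameters=tuple(s for s in cols if s in params),
    )


def _independent_rows(mat: sp.Matrix, seed: int = 0) -> list[int]:
    """Indices of a maximal independent row subset (found numerically)."""
    from .series import exponent_symbols

    symbols = sorted(mat.free_symbols, key=lambda s: s.name)
    point = random_point(symbols, seed, small=exponent_symbols(list(mat)))
    subs = {s: sp.Rational(v) for s, v in point.assignment.items()}
    from fractions import Fraction

    rows = []
    for i in range(mat.rows):
        row = []
        for j in range(mat.cols):
            v = sp.cancel(mat[i, j]).xreplace(subs)
            if not v.is_Rational:
                v = sp.nsimplify(v, rational=True)
            row.append(Fraction(int(v.p), int(v.q)))
        rows.append(row)
    chosen: list[int] = []
    rank = 0
    for i in range(len(rows)):
        cand = [rows[k] for k in chosen] + [rows[i]]
        r = rational_rank(cand)
        if r > rank:
            chosen.append(i)
            rank = r
        if rank == mat.cols:
            break
    return chosen


def kernel_basis(reduced: ReducedMatrix, seed: int = 0) -> list[KernelVector]:
    """Symbolic basis of the right null space of ``O_U``.

    The null space is computed on a maximal independent subset of rows
    (located numerically, which is exact w.h.p. and verified symbolically
    afterwards) and each basis vector is normalised so its last nonzero
    entry is 1.
    """
    mat = reduced.matrix
    rows = _independent_rows(mat, seed)
    sub = mat[rows, :]
    basis = sub.applyfunc(sp.cancel).nullspace(simplify=True)
    out = []
    for v in basis:
        entries = [sp.cancel(sp.together(e)) for e in v]
        last = None
        for e in reversed(entries):
            if e != 0:
                last = e
                break
        if last is not None:
            entries = [sp.cancel(e / last) for e in entries]
        vec = KernelVector(
            coefficients=tuple(entries), columns=reduced.columns
        )
        # verify against the *full* reduced matrix, not just the row subset
        residual = mat * sp.Matrix(entries)
        for r in residual:
            if sp.simplify(sp.cancel(sp.together(r))) != 0:
                raise ArithmeticError(
                    "kernel vector fails verification on the full matrix"
                )
        out.append(vec)
    return out


def _pair_solution(pa: sp.Symbol, pb: sp.Symbol, va: sp.Expr, vb: sp.Expr):
    """First integral of va*dPhi/dpa + vb*dPhi/dpb = 0 for monomial ratios.

    Characteristics: dpa/dpb = va/vb =: w(pa, pb).  Supported separable
    monomial shapes  w = c * pa^alpha * pb^beta  integrate in closed form.
    """
    w = sp.cancel(sp.together(va / vb))
    c, alpha, beta = _as_monomial(w, pa, pb)
    if c is None:
        return None
    # dpa / pa^alpha = c * pb^beta dpb
    if alpha == 1 and beta == -1:
        # log pa = c log pb  ->  Phi = pa / pb^c
        expr = pa / pb**c if c != -1 else pa * pb
    elif alpha == 0 and beta == 0:
        # linear: vb*pa - va*pb with constant coefficients
        expr = pa - c * pb
    elif alpha == 1:
        expr = sp.log(pa) - c * pb**(beta + 1) / (beta + 1)
        expr = sp.exp(expr)  # pa * exp(-c pb^{beta+1}/(beta+1))
        expr = sp.powsimp(expr)
    elif beta == -1:
        expr = pa**(1 - alpha) / (1 - alpha) - c * sp.log(pb)
    else:
        expr = (
            pa**(1 - alpha) / (1 - alpha)
            - c * pb**(beta + 1) / (beta + 1)
        )
    return sp.cancel(sp.powsimp(expr, force=False))


def _as_monomial(w: sp.Expr, pa: sp.Symbol, pb: sp.Symbol):
    """Write w as c * pa^alpha * pb^beta with c free of pa, pb."""
    for alpha in (0, 1, -1, 2, -2):
        for beta in (0, 1, -1, 2, -2):
            c = sp.cancel(w / (pa**alpha * pb**beta))
            if not (c.free_symbols & {pa, pb}):
                return c, alpha, beta
    return None, None, None


def solve_combination(vector: KernelVector) -> Combination:
    """Solve the PDE generated by a kernel vector by characteristics.

    Vectors with a single nonzero entry indicate a completely free
    parameter (no combination exists); vectors with two nonzero entries of
    constant or monomial-ratio shape are solved in closed form; everything
    else is returned unsolved.  Every solved combination is verified by
    substitution into the PDE.
    """
    support = [
        (s, c) for s, c in zip(vector.columns, vector.coefficients) if c != 0
    ]
    pde = sp.Add(*[
        c * sp.Symbol(f"dPhi_d{s.name}") for s, c in support
    ])
    if len(support) < 2:
        return Combination(
            expression=None, solved=False, pde=pde, vector=vector
        )
    expr = None
    if len(support) == 2:
        (pa, va), (pb, vb) = support
        expr = _pair_solution(pa, pb, va, vb)
    elif all(not c.free_symbols for _, c in support):
        # constant coefficients: any orthogonal linear form works; return
        # the pairwise form anchored on the last entry
        (pa, va), (pb, vb) = support[-2], support[-1]
        expr = vb * pa - va * pb
    if expr is None:
        return Combination(
            expression=None, solved=False, pde=pde, vector=vector
        )
    # verification: sum_i v_i dPhi/dp_i == 0 identically
    residual = sp.simplify(sp.together(sp.Add(*[
        c * sp.diff(expr, s) for s, c in support
    ])))
    if residual != 0:
        return Combination(
            expression=None, solved=False, pde=pde, vector=vector
        )
    return Combination(expression=expr, solved=True, pde=pde, vector=vector)


def find_combinations(
    oi: OIMatrix, classification: Classification, seed: int = 0
) -> list[Combination]:
    """Kernel-based combination search on the reduced matrix ``O_U``.

    Parameter-only kernel vectors are solved for combinations; vectors
    mixing states and parameters are reported as symmetries (unsolved).
    """
    reduced = reduce_to_unidentifiable(oi, classification)
    combos = []
    for vec in kernel_basis(reduced, seed=seed):
        if vec.parameters_only(reduced.parameters):
            combos.append(solve_combination(vec))
        else:
            combos.append(Combination(
                expression=None, solved=False,
                pde=sp.Integer(0), vector=vec, kind="symmetry",
            ))
    return combos
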