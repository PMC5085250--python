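"""Exact evaluation of Lie-derivative Jacobians at rational points.

The observability-identifiability (OI) matrix stacks the Jacobians of the
Lie derivatives ``L_f^i g`` with respect to the augmented state
``x_tilde = [x, p]``.  Its *generic* rank can be obtained by evaluating the
matrix at a random point with each symbol replaced by a distinct prime and
computing the rank in exact arithmetic; symbolic entries are never needed
for the rank itself.

Building the huge symbolic entries first and substituting afterwards is
wasteful: expression swell makes high orders intractable.  This module
instead exploits the identity ``L_f^i g = d^i/dt^i g(x(t))`` along the flow
of the (augmented) vector field: the output trajectory is propagated as a
truncated Taylor series in ``t`` whose coefficients are first-order dual
numbers carrying d/d(x_tilde) sensitivities, all over exact ``Fraction``
arithmetic.  Row ``i`` of the OI matrix is then ``i!`` times the gradient
part of the ``i``-th Taylor coefficient of the output.  The result is
*identical* to prime substitution into the symbolic matrix, at a cost that
is polynomial in the derivative order.

Transcendental constants produced at the evaluation point (``log`` or
``exp`` of a rational, the value of ``sin``/``cos`` at a rational angle, a
non-integer rational power) are algebraically independent of the rationals;
they are replaced by fresh random rational surrogates, drawn once per trial
(a sine/cosine pair shares a random rational point on the unit circle so
that sin^2 + cos^2 = 1 is preserved).  A measure-zero set of unlucky draws
can lower the observed rank, never raise it; repeating the evaluation over
several independent trials and keeping the maximum rank makes a spurious
verdict vanishingly unlikely.
"""

from __future__ import annotations

import random
from fractions import Fraction
from typing import Sequence

import sympy as sp

__all__ = [
    "DegeneratePointError",
    "Domain",
    "EvaluationPoint",
    "exponent_symbols",
    "random_point",
    "oi_blocks_at_point",
    "matrix_rank_rows",
    "rational_rank",
    "rank_without_columns",
]


class DegeneratePointError(ArithmeticError):
    """The chosen evaluation point hits a pole of the model expressions."""


_PRIMES = list(sp.primerange(2, 3000))


# ---------------------------------------------------------------------------
# Coefficient domains: exact rationals, or a prime field GF(p)
# ---------------------------------------------------------------------------
#
# All rank conclusions are one-sided (a specialised matrix can only lose
# rank, never gain it), so evaluating over GF(p) with a random 62-bit p per
# trial is as sound as rational arithmetic while avoiding gcd-heavy bigint
# growth; the multi-trial maximum rank absorbs unlucky reductions.  The
# rational domain remains available for cross-checks.

class _GFElement:
    __slots__ = ("v",)
    p = None  # overridden per-field subclass

    def __init__(self, v: int):
        self.v = v % self.p

    @classmethod
    def _coerce(cls, o):
        if isinstance(o, cls):
            return o.v
        if isinstance(o, int):
            return o % cls.p
        if isinstance(o, Fraction):
            den = o.denominator % cls.p
            if den == 0:
                raise DegeneratePointError("denominator divisible by field prime")
            return o.numerator * pow(den, cls.p - 2, cls.p) % cls.p
        return NotImplemented

    def __add__(self, o):
        w = self._coerce(o)
        return NotImplemented if w is NotImplemented else type(self)(self.v + w)

    __radd__ = __add__

    def __sub__(self, o):
        w = self._coerce(o)
        return NotImplemented if w is NotImplemented else type(self)(self.v - w)

    def __rsub__(self, o):
        w = self._coerce(o)
        return NotImplemented if w is NotImplemented else type(self)(w - self.v)

    def __mul__(self, o):
        w = self._coerce(o)
        return NotImplemented if w is NotImplemented else type(self)(self.v * w)

    __rmul__ = __mul__

    def __truediv__(self, o):
        w = self._coerce(o)
        if w is NotImplemented:
            return NotImplemented
        if w == 0:
            raise DegeneratePointError("division by zero in GF(p)")
        return type(self)(self.v * pow(w, self.p - 2, self.p))

    def __rtruediv__(self, o):
        if self.v == 0:
            raise DegeneratePointError("division by zero in GF(p)")
        w = self._coerce(o)
        return type(self)(w * pow(self.v, self.p - 2, self.p))

    def __neg__(self):
        return type(self)(-self.v)

    def __eq__(self, o):
        if isinstance(o, int):
            return self.v == o % self.p
        if isinstance(o, _GFElement):
            return self.v == o.v
        return NotImplemented

    def __hash__(self):
        return hash((self.p, self.v))

    def __repr__(self):
        return f"GF({self.p})[{self.v}]"


class Domain:
    """Coefficient domain for point evaluation: rationals or GF(p)."""

    def __init__(self, prime: int | None = None):
        self.prime = prime
        if prime is None:
            self._cls = None
        else:
            self._cls = type(f"_GF{prime}", (_GFElement,), {"p": prime})

    def convert(self, value):
        if self._cls is None:
            return value if isinstance(value, Fraction) else Fraction(value)
        return (
            self._cls(value) if isinstance(value, int)
            else self._cls(self._cls._coerce(Fraction(value)))
        )

    def zero(self):
        return self.convert(0)

    def one(self):
        return self.convert(1)

    @staticmethod
    def random_field(rng: random.Random) -> "Domain":
        candidate = rng.randrange(2**61, 2**62) | 1
        while not _is_probable_prime(candidate):
            candidate += 2
        return Domain(candidate)


def _is_probable_prime(n: int) -> bool:
    # deterministic Miller-Rabin for n < 3.3e24 with the first 13 primes
    if n < 2:
        return False
    for p in (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41):
        if n % p == 0:
            return n == p
    d, r = n - 1, 0
    while d % 2 == 0:
        d //= 2
        r += 1
    for a in (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41):
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(r - 1):
            x = x * x % n
            if x == n - 1:
                break
        else:
            return False
    return True


class _Dual:
    """First-order dual number: value plus gradient w.r.t. x_tilde."""

    __slots__ = ("v", "g")

    def __init__(self, v: Fraction, g: tuple):
        self.v = v
        self.g = g

    def __add__(self, o):
        if isinstance(o, _Dual):
            return _Dual(self.v + o.v, tuple(a + b for a, b in zip(self.g, o.g)))
        return _Dual(self.v + o, self.g)

    __radd__ = __add__

    def __sub__(self, o):
        if isinstance(o, _Dual):
            return _Dual(self.v - o.v, tuple(a - b for a, b in zip(self.g, o.g)))
        return _Dual(self.v - o, self.g)

    def __rsub__(self, o):
        return _Dual(o - self.v, tuple(-a for a in self.g))

    def __mul__(self, o):
        if isinstance(o, _Dual):
            return _Dual(
                self.v * o.v,
                tuple(self.v * b + o.v * a for a, b in zip(self.g, o.g)),
            )
        return _Dual(self.v * o, tuple(a * o for a in self.g))

    __rmul__ = __mul__

    def __truediv__(self, o):
        if isinstance(o, _Dual):
            if o.v == 0:
                raise DegeneratePointError("division by zero at evaluation point")
            iv = Fraction(1) / o.v
            v = self.v * iv
            return _Dual(v, tuple((a - v * b) * iv for a, b in zip(self.g, o.g)))
        if o == 0:
            raise DegeneratePointError("division by zero at evaluation point")
        return _Dual(self.v / o, tuple(a / o for a in self.g))

    def __neg__(self):
        return _Dual(-self.v, tuple(-a for a in self.g))

    def scale(self, c):
        return _Dual(self.v * c, tuple(a * c for a in self.g))

    def is_exact_zero(self) -> bool:
        return self.v == 0 and all(a == 0 for a in self.g)


def _dzero(dim: int, domain: "Domain") -> _Dual:
    z = domain.zero()
    return _Dual(z, (z,) * dim)


def _dconst(c, dim: int, domain: "Domain") -> _Dual:
    return _Dual(domain.convert(c), (domain.zero(),) * dim)


# -- truncated Taylor series over duals -------------------------------------

def _smul(a, b):
    n = len(a)
    out = []
    for k in range(n):
        s = a[0] * b[k]
        for i in range(1, k + 1):
            s = s + a[i] * b[k - i]
        out.append(s)
    return out


def _sdiv(a, b):
    n = len(a)
    out = []
    for k in range(n):
        s = a[k]
        for i in range(k):
            s = s - out[i] * b[k - i]
        out.append(s / b[0])
    return out


class EvaluationPoint:
    """A rational-valued assignment of every model symbol.

    ``assignment`` maps symbols to Fractions.  ``rng`` supplies the random
    surrogates for transcendental constants, cached per (function, argument)
    so repeated occurrences of the same constant stay consistent.
    """

    def __init__(self, assignment: dict, rng: random.Random):
        self.assignment = dict(assignment)
        self._rng = rng
        self._surrogates: dict = {}

    def surrogate(self, kind: str, value: Fraction) -> Fraction:
        key = (kind, value)
        if key not in self._surrogates:
            num = self._rng.randrange(2, 10**6)
            den = self._rng.randrange(2, 10**6)
            self._surrogates[key] = Fraction(num, den)
        return self._surrogates[key]

    def trig_surrogate(self, value: Fraction) -> tuple[Fraction, Fraction]:
        key = ("trig", value)
        if key not in self._surrogates:
            t = Fraction(self._rng.randrange(2, 10**6),
                         self._rng.randrange(2, 10**6))
            sin0 = 2 * t / (1 + t * t)
            cos0 = (1 - t * t) / (1 + t * t)
            self._surrogates[key] = (sin0, cos0)
        return self._surrogates[key]


_SMALL_PRIMES = [2, 3, 5, 7, 11, 13]


def exponent_symbols(exprs) -> set:
    """Symbols that occur inside an exponent somewhere in ``exprs``.

    Point values for these must stay small: a symbolic Hill exponent that
    drew a prime like 2741 would raise series arithmetic to that power.
    """
    found: set = set()
    for expr in exprs:
        for pw in sp.sympify(expr).atoms(sp.Pow):
            found |= pw.exp.free_symbols
    return found


def random_point(
    symbols: Sequence[sp.Symbol],
    seed: int,
    fixed: dict | None = None,
    small: set | None = None,
) -> EvaluationPoint:
    """Assign a distinct random prime to every symbol (``fixed`` overrides).

    Symbols in ``small`` (typically exponents) draw from the small primes;
    the rest draw from primes above 31, so the two pools never collide.
    """
    rng = random.Random(seed)
    small = set(small or ())
    small_syms = [s for s in symbols if s in small]
    big_syms = [s for s in symbols if s not in small]
    if len(small_syms) > len(_SMALL_PRIMES):
        raise ValueError("too many exponent symbols for the small-prime pool")
    assignment = {}
    for s, p in zip(small_syms, rng.sample(_SMALL_PRIMES, len(small_syms))):
        assignment[s] = Fraction(p)
    # the smallest primes that keep the pools disjoint: bigint growth in the
    # series arithmetic scales with the point values raised to Hill exponents
    big_pool = [p for p in _PRIMES if p > 13][: len(big_syms) + 8]
    for s, p in zip(big_syms, rng.sample(big_pool, len(big_syms))):
        assignment[s] = Fraction(p)
    for s, v in (fixed or {}).items():
        assignment[s] = Fraction(sp.nsimplify(v, rational=True))
    return EvaluationPoint(assignment, rng)


class _SeriesEvaluator:
    def __init__(self, point: EvaluationPoint, dim: int, length: int,
                 domain: "Domain", column_set=frozenset()):
        self.point = point
        self.dim = dim
        self.length = length
        self.domain = domain
        self.columns = column_set
        self.env: dict = {}

    def constant(self, value) -> list:
        return [
            _dconst(value, self.dim, self.domain)
        ] + [_dzero(self.dim, self.domain)] * (self.length - 1)

    def _surrogate(self, kind, value):
        return self.domain.convert(self.point.surrogate(kind, value))

    def evaluate(self, expr: sp.Expr) -> list:
        if expr.is_Symbol:
            try:
                return self.env[expr]
            except KeyError:
                raise DegeneratePointError(f"no value for symbol {expr}")
        if expr is sp.pi:
            return self.constant(self.point.surrogate("pi", 0))
        if expr.is_Number:
            return self.constant(Fraction(sp.Rational(expr)))
        if expr.is_Add:
            parts = [self.evaluate(a) for a in expr.args]
            out = parts[0]
            for p in parts[1:]:
                out = [x + y for x, y in zip(out, p)]
            return out
        if expr.is_Mul:
            parts = [self.evaluate(a) for a in expr.args]
            out = parts[0]
            for p in parts[1:]:
                out = _smul(out, p)
            return out
        if expr.is_Pow:
            if expr.exp.is_Integer:
                return self._int_pow(self.evaluate(expr.base), int(expr.exp))
            if (
                expr.exp.is_Symbol
                and expr.exp not in self.columns
                and self.point.assignment.get(expr.exp, Fraction(1, 2)
                                              ).denominator == 1
            ):
                # known-constant integer exponent (no sensitivity column)
                return self._int_pow(
                    self.evaluate(expr.base),
                    int(self.point.assignment[expr.exp]),
                )
            base = self.evaluate(expr.base)
            expo = self.evaluate(expr.exp)
            if any(not c.is_exact_zero() for c in expo[1:]):
                # time-varying exponent: f^h = exp(h log f)
                return self._exp(_smul(expo, self._log(base)))
            lg = self._log(base)
            return self._exp([c * expo[0] for c in lg])
        if expr.func is sp.exp:
            return self._exp(self.evaluate(expr.args[0]))
        if expr.func is sp.log:
            return self._log(self.evaluate(expr.args[0]))
        if expr.func is sp.sin:
            return self._sincos(self.evaluate(expr.args[0]))[0]
        if expr.func is sp.cos:
            return self._sincos(self.evaluate(expr.args[0]))[1]
        raise NotImplementedError(
            f"unsupported operation {expr.func} in expression {expr}"
        )

    def _int_pow(self, base: list, n: int) -> list:
        out = self.constant(1)
        b = base
        e = abs(n)
        while e:
            if e & 1:
                out = _smul(out, b)
            b = _smul(b, b)
            e >>= 1
        if n < 0:
            out = _sdiv(self.constant(1), out)
        return out

    def _log(self, a: list) -> list:
        if a[0].v == 0:
            raise DegeneratePointError("log of zero at evaluation point")
        c0 = _Dual(
            self._surrogate("log", a[0].v),
            tuple(x / a[0].v for x in a[0].g),
        )
        out = [c0]
        for k in range(1, self.length):
            s = a[k].scale(k)
            for i in range(1, k):
                s = s - out[i].scale(i) * a[k - i]
            out.append((s / a[0]).scale(Fraction(1, k)))
        return out

    def _exp(self, a: list) -> list:
        e0v = self._surrogate("exp", a[0].v)
        e0 = _Dual(e0v, tuple(e0v * x for x in a[0].g))
        out = [e0]
        for k in range(1, self.length):
            s = out[0] * a[k].scale(k)
            for i in range(1, k):
                s = s + out[i] * a[k - i].scale(k - i)
            out.append(s.scale(Fraction(1, k)))
        return out

    def _sincos(self, a: list) -> tuple[list, list]:
        sin0f, cos0f = self.point.trig_surrogate(a[0].v)
        sin0v = self.domain.convert(sin0f)
        cos0v = self.domain.convert(cos0f)
        s0 = _Dual(sin0v, tuple(cos0v * x for x in a[0].g))
        c0 = _Dual(cos0v, tuple(-sin0v * x for x in a[0].g))
        sins, coss = [s0], [c0]
        # k*sin_k = sum_{i<k} cos_i * (k-i) a_{k-i};  k*cos_k = -sum sin_i * ...
        for k in range(1, self.length):
            ss = coss[0] * a[k].scale(k)
            cc = sins[0] * a[k].scale(k)
            for i in range(1, k):
                ss = ss + coss[i] * a[k - i].scale(k - i)
                cc = cc + sins[i] * a[k - i].scale(k - i)
            sins.append(ss.scale(Fraction(1, k)))
            coss.append(cc.scale(Fraction(-1, k)))
        return sins, coss


def oi_blocks_at_point(
    states: Sequence[sp.Symbol],
    columns: Sequence[sp.Symbol],
    odes: Sequence[sp.Expr],
    outputs: Sequence[sp.Expr],
    point: EvaluationPoint,
    n_orders: int,
    extra_symbols: Sequence[sp.Symbol] = (),
    input_series: dict | None = None,
    domain: Domain | None = None,
) -> list[list[list]]:
    """Evaluate OI blocks 0..n_orders at ``point``.

    ``columns`` are the symbols the Jacobians are taken against (the
    augmented state).  ``extra_symbols`` (inputs, known constants, fixed
    parameters) receive point values but no gradient column.
    ``input_series`` optionally maps an input symbol to the list of its
    time-derivative values at t=0 (analytic-input mode); inputs default to
    constants.  ``domain`` selects the coefficient arithmetic (exact
    rationals by default, or a prime field).

    Returns ``n_orders + 1`` blocks, each ``m x len(columns)``.
    """
    domain = domain or Domain()
    dim = len(columns)
    length = n_orders + 2  # series coefficients 0 .. n_orders (+1 headroom)
    ev = _SeriesEvaluator(point, dim, length, domain, frozenset(columns))
    col_index = {s: j for j, s in enumerate(columns)}
    zero, one = domain.zero(), domain.one()

    def seed_dual(sym: sp.Symbol) -> _Dual:
        v = point.assignment[sym]
        grad = [zero] * dim
        if sym in col_index:
            grad[col_index[sym]] = one
        return _Dual(domain.convert(v), tuple(grad))

    # non-state symbols: constant series (parameters keep their gradient)
    for sym in columns:
        if sym not in states:
            ev.env[sym] = [seed_dual(sym)] + [_dzero(dim, domain)] * (length - 1)
    for sym in extra_symbols:
        if sym in ev.env:
            continue
        if input_series and sym in input_series:
            coeffs = []
            fact = 1
            for k, dval in enumerate(input_series[sym]):
                if k:
                    fact *= k
                coeffs.append(_dconst(Fraction(dval, fact), dim, domain))
            coeffs += [_dzero(dim, domain)] * (length - len(coeffs))
            ev.env[sym] = coeffs[:length]
        else:
            ev.env[sym] = [_dconst(point.assignment[sym], dim, domain)] + \
                [_dzero(dim, domain)] * (length - 1)

    # propagate the state trajectory one Taylor coefficient at a time
    xser = {s: [seed_dual(s)] for s in states}
    for k in range(length - 1):
        for s in states:
            ev.env[s] = xser[s] + [_dzero(dim, domain)] * (length - len(xser[s]))
        for s, f_expr in zip(states, odes):
            fk = ev.evaluate(f_expr)[k]
            xser[s].append(fk.scale(Fraction(1, k + 1)))
    for s in states:
        ev.env[s] = xser[s]

    blocks: list[list[list]] = []
    yser = [ev.evaluate(g) for g in outputs]
    fact = 1
    for order in range(n_orders + 1):
        if order:
            fact *= order
        block = [
            [ys[order].g[j] * fact for j in range(dim)]
            for ys in yser
        ]
        blocks.append(block)
    return blocks


# ---------------------------------------------------------------------------
# Exact rank of rational matrices
# ---------------------------------------------------------------------------

def matrix_rank_rows(rows: list[list]) -> int:
    """Rank of a matrix of Fractions or GF(p) elements (exact)."""
    if not rows:
        return 0
    if isinstance(rows[0][0], _GFElement):
        return _gf_rank(rows)
    return rational_rank(rows)


def _gf_rank(rows: list[list[_GFElement]]) -> int:
    p = type(rows[0][0]).p
    mat = [[e.v for e in row] for row in rows]
    n_rows, n_cols = len(mat), len(mat[0])
    rank = 0
    for col in range(n_cols):
        piv = None
        for i in range(rank, n_rows):
            if mat[i][col]:
                piv = i
                break
        if piv is None:
            continue
        mat[rank], mat[piv] = mat[piv], mat[rank]
        inv = pow(mat[rank][col], p - 2, p)
        for i in range(rank + 1, n_rows):
            vi = mat[i][col]
            if vi:
                f = vi * inv % p
                mat[i] = [
                    (a - f * b) % p for a, b in zip(mat[i], mat[rank])
                ]
        rank += 1
        if rank == n_rows:
            break
    return rank


def rational_rank(rows: list[list[Fraction]]) -> int:
    """Rank of a matrix of Fractions by fraction-free Gaussian elimination."""
    if not rows:
        return 0
    # clear denominators row-wise -> integer matrix
    mat = []
    for row in rows:
        den = 1
        for x in row:
            den = den * x.denominator // _gcd(den, x.denominator)
        ints = [int(x * den) for x in row]
        g = 0
        for v in ints:
            g = _gcd(g, abs(v))
        if g > 1:
            ints = [v // g for v in ints]
        mat.append(ints)
    n_rows, n_cols = len(mat), len(mat[0])
    rank = 0
    for col in range(n_cols):
        piv = None
        for i in range(rank, n_rows):
            if mat[i][col]:
                piv = i
                break
        if piv is None:
            continue
        mat[rank], mat[piv] = mat[piv], mat[rank]
        pv = mat[rank][col]
        for i in range(rank + 1, n_rows):
            vi = mat[i][col]
            if vi:
                row = [pv * a - vi * b for a, b in zip(mat[i], mat[rank])]
                g = 0
                for v in row:
                    g = _gcd(g, abs(v))
                if g > 1:
                    row = [v // g for v in row]
                mat[i] = row
        rank += 1
        if rank == n_rows:
            break
    return rank


def rank_without_columns(rows: list[list], remove: set[int]) -> int:
    kept = [j for j in range(len(rows[0]))] if rows else []
    kept = [j for j in kept if j not in remove]
    return matrix_rank_rows([[row[j] for j in kept] for row in rows])


def _gcd(a: int, b: int) -> int:
    while b:
        a, b = b, a % b
    return a
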