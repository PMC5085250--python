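"""Kernel of the reduced matrix O_U and identifiable combinations."""

import pytest
import sympy as sp

import strucid as si
from strucid import UNIDENTIFIABLE
from strucid.combos import (
    KernelVector,
    find_combinations,
    kernel_basis,
    reduce_to_unidentifiable,
    solve_combination,
)
from strucid.lie import symbolic_blocks

from conftest import make_model


def _sym_analysis(model, orders, opts=None):
    opts = opts or si.AnalysisOptions(seed=1)
    aug = si.augment(model)
    num = si.build_oi(aug, opts)
    cls = si.classify_elements(num, aug)
    sym = symbolic_blocks(aug, orders)
    return sym, cls


@pytest.fixture(scope="module")
def sum_pair_model():
    return make_model("sum_pair", ["x"], ["p1", "p2"], [],
                      ["-x"], ["(p1 + p2)*x"])


@pytest.fixture(scope="module")
def product_pair_model():
    return make_model("prod_pair", ["x"], ["p1", "p2"], [],
                      ["p1*p2*x - x"], ["x"])


def test_sum_pair_kernel_and_combination(sum_pair_model):
    sym, cls = _sym_analysis(sum_pair_model, 2)
    reduced = reduce_to_unidentifiable(sym, cls)
    assert [s.name for s in reduced.columns] == ["p1", "p2"]
    basis = kernel_basis(reduced)
    assert len(basis) == reduced.matrix.cols - 1
    combo = solve_combination(basis[0])
    assert combo.solved
    p1, p2 = sp.symbols("p1 p2")
    assert sp.simplify(combo.expression - (p1 + p2)) == 0 or \
        sp.simplify(combo.expression + (p1 + p2)) == 0


def test_product_pair_combination(product_pair_model):
    sym, cls = _sym_analysis(product_pair_model, 2)
    combos = find_combinations(sym, cls)
    solved = [c for c in combos if c.solved]
    assert len(solved) == 1
    p1, p2 = sp.symbols("p1 p2")
    assert sp.simplify(solved[0].expression - p1 * p2) == 0


def test_state_parameter_symmetry_reported_not_solved(scale_toy, opts):
    sym, cls = _sym_analysis(scale_toy, 1, opts)
    reduced = reduce_to_unidentifiable(sym, cls, include_states=True)
    assert {s.name for s in reduced.columns} == {"x", "p"}
    basis = kernel_basis(reduced)
    assert len(basis) == 1
    x, p = sp.Symbol("x"), sp.Symbol("p")
    v = sp.Matrix(list(basis[0].coefficients))
    # the kernel vector is [x, -p] up to normalisation
    assert sp.simplify(v[0] * (-p) - v[1] * x) == 0
    combo = solve_combination(basis[0])
    assert combo.solved
    assert sp.simplify(combo.expression - x * p) == 0


def test_solved_combinations_satisfy_their_pde():
    # direct characteristics checks on hand-built kernel vectors
    p1, p2 = sp.symbols("p1 p2")
    cases = [
        ((sp.Integer(1), sp.Integer(-1)), (p1, p2)),
        ((-p1 / p2, sp.Integer(1)), (p1, p2)),
        ((p1, -p2), (p1, p2)),
    ]
    for coeffs, cols in cases:
        combo = solve_combination(
            KernelVector(coefficients=coeffs, columns=cols)
        )
        assert combo.solved
        residual = sum(
            c * sp.diff(combo.expression, s) for s, c in zip(cols, coeffs)
        )
        assert sp.simplify(residual) == 0


def test_single_entry_vector_has_no_combination():
    p1, p2 = sp.symbols("p1 p2")
    combo = solve_combination(
        KernelVector(coefficients=(sp.Integer(1), sp.Integer(0)),
                     columns=(p1, p2))
    )
    assert not combo.solved


def test_reduce_requires_a_deficient_matrix(opts):
    m = make_model("decay", ["x"], ["k"], [], ["-k*x"], ["x"])
    sym, cls = _sym_analysis(m, 1, opts)
    with pytest.raises(ValueError, match="already identifiable"):
        reduce_to_unidentifiable(sym, cls)


def test_jakstat_combination_closure(jakstat):
    """Reparameterizing with the found combination makes it identifiable."""
    opts = si.AnalysisOptions(seed=4)
    cls = si.analyze_model(jakstat, opts)
    from strucid.workflow import _combinations_for

    combos = [c for c in _combinations_for(jakstat, cls, opts) if c.solved]
    assert len(combos) == 1
    th17, th22 = jakstat.symbol("th17"), jakstat.symbol("th22")
    assert sp.simplify(combos[0].expression - th17 * th22) == 0
    phi = sp.Symbol("Phi")
    m2 = si.reparameterize(
        jakstat, fix={jakstat.symbol("th11"): 1.0},
        substitute={(th17, th22): (phi, th17 * th22)},
    )
    cls2 = si.analyze_model(m2, opts)
    assert cls2.rank_verdicts[phi] == si.IDENTIFIABLE
    assert UNIDENTIFIABLE not in set(cls2.per_element.values())
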