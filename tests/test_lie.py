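"""Lie derivatives, n_d, the OI matrix build, and rank computation."""

import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

import strucid as si
from strucid.lie import input_derivative_symbol, symbolic_blocks

from conftest import make_model


# -- n_d --------------------------------------------------------------------

@pytest.mark.parametrize("n, q, m, expected", [
    (3, 8, 1, 10),
    (7, 18, 2, 12),
    (1, 0, 1, 0),
    (10, 23, 8, 4),
])
def test_minimum_derivative_order(n, q, m, expected):
    assert si.compute_nd(n, q, m) == expected


@settings(max_examples=200, derandomize=True)
@given(st.integers(1, 60), st.integers(0, 120), st.integers(1, 20))
def test_nd_is_smallest_order_with_enough_rows(n, q, m):
    nd = si.compute_nd(n, q, m)
    # m*(nd+1) rows suffice for rank n+q, and one order less does not
    assert m * (nd + 1) >= n + q
    assert nd == 0 or m * nd < n + q


def test_nd_rejects_degenerate_dimensions():
    with pytest.raises(ValueError):
        si.compute_nd(0, 1, 1)
    with pytest.raises(ValueError):
        si.compute_nd(1, 1, 0)


# -- Lie derivatives --------------------------------------------------------

def test_angle_sensor_first_lie_derivative(angle_sensor):
    aug = si.augment(angle_sensor)
    x, u = sp.Symbol("x"), sp.Symbol("u")
    assert si.lie_derivative(aug, 0) == [sp.cos(x), sp.sin(x)]
    d1 = si.lie_derivative(aug, 1)
    assert sp.simplify(d1[0] + u * sp.sin(x)) == 0
    assert sp.simplify(d1[1] - u * sp.cos(x)) == 0


def test_lie_derivative_of_state_free_output_vanishes():
    m = make_model("const_out", ["x"], ["p"], [], ["p*x"], ["p"])
    aug = si.augment(m)
    for order in (1, 2, 3):
        assert all(e == 0 for e in si.lie_derivative(aug, order))


def test_linear_system_lie_derivatives_follow_kalman_powers():
    # dx/dt = A x, y = C x with known entries: L^i g = C A^i x
    x1, x2, x3 = sp.symbols("x1 x2 x3")
    m = make_model(
        "lti", ["x1", "x2", "x3"], [], [],
        ["2*x2 - x1", "x3", "-3*x1"], ["x1 + x2"],
    )
    A = sp.Matrix([[-1, 2, 0], [0, 0, 1], [-3, 0, 0]])
    C = sp.Matrix([[1, 1, 0]])
    aug = si.augment(m)
    xvec = sp.Matrix([x1, x2, x3])
    for i in range(4):
        expected = (C * A**i * xvec)[0]
        assert sp.expand(si.lie_derivative(aug, i)[0] - expected) == 0


def test_input_derivative_chain_rule():
    # dx/dt = u, y = x: L1 = u, L2 = u' when inputs are analytic functions,
    # and 0 in constant-input mode
    m = make_model("integrator", ["x"], [], ["u"], ["u"], ["x"])
    aug = si.augment(m)
    u = sp.Symbol("u")
    assert si.lie_derivative(aug, 2, input_derivative_order=0) == [0]
    l2 = si.lie_derivative(aug, 2, input_derivative_order=2)
    assert l2 == [input_derivative_symbol(u, 1)]
    l3 = si.lie_derivative(aug, 3, input_derivative_order=2)
    assert l3 == [input_derivative_symbol(u, 2)]
    # derivatives beyond the declared order are zero
    assert si.lie_derivative(aug, 4, input_derivative_order=2) == [0]


# -- build + stopping rules -------------------------------------------------

def test_scale_toy_rank_stalls_below_full(scale_toy, opts):
    res = si.oic_test(scale_toy, opts)
    assert res.verdict == "rank_deficient"
    assert res.rank == 1
    assert res.full_rank_needed == 2
    assert res.oi.stop_reason in ("rank_stalled", "max_order")


def test_kalman_chain_is_observable(opts):
    m = make_model("chain", ["x1", "x2"], [], [], ["x2", "0"], ["x1"])
    res = si.oic_test(m, opts)
    assert res.identifiable
    assert res.rank == 2


def test_angle_sensor_locally_observable_at_order_zero(angle_sensor, opts):
    res = si.oic_test(angle_sensor, opts)
    assert res.identifiable
    assert res.orders_used == 0
    assert res.oi.stop_reason == "full_rank"


def test_rank_of_proportional_rows_in_both_modes(scale_toy):
    # block 0 for y = p*x over columns (x, p) is [p, x]; adding the
    # proportional row [2p, 2x] must not raise the rank
    aug = si.augment(scale_toy)
    oi = symbolic_blocks(aug, 0)
    x, p = sp.Symbol("x"), sp.Symbol("p")
    oi.blocks = [sp.Matrix([[p, x], [2 * p, 2 * x]])]
    assert si.matrix_rank(oi, mode="symbolic") == 1
    assert si.matrix_rank(oi, mode="numeric", trials=2, seed=0) == 1


def test_numeric_rank_never_exceeds_symbolic(scale_toy, goodwin):
    for model, orders in ((scale_toy, 2), (goodwin, 2)):
        aug = si.augment(model)
        oi = symbolic_blocks(aug, orders)
        sym = si.matrix_rank(oi, mode="symbolic")
        for seed in range(3):
            num = si.matrix_rank(oi, mode="numeric", trials=1, seed=seed)
            assert num <= sym


def test_budget_breach_is_recorded_not_raised(goodwin):
    opts = si.AnalysisOptions(seed=0, rank_mode="symbolic",
                              max_lie_seconds=1e-9)
    oi = si.build_oi(si.augment(goodwin), opts)
    assert oi.stop_reason == "budget"
    assert oi.order_built < 10


def test_rank_history_monotone_and_bounded(goodwin, jakstat, opts):
    for model in (goodwin, jakstat):
        aug = si.augment(model)
        oi = si.build_oi(aug, opts)
        orders = sorted(oi.rank_history)
        ranks = [oi.rank_history[o] for o in orders]
        assert ranks == sorted(ranks)
        for o in orders:
            assert oi.rank_history[o] <= min(model.m * (o + 1), aug.dim)
        if oi.stop_reason == "rank_stalled":
            assert ranks[-1] == ranks[-2]


def test_known_ic_mode_uses_supplied_initial_conditions():
    # y = x2 driven by p*x1 with nonlinear decay of x1: generically fine,
    # but from x1(0) = 0 the driving state never moves and p is invisible
    m = make_model(
        "ic_loss", ["x1", "x2"], ["p"], [],
        ["-x1^2", "p*x1 - x2"], ["x2"],
        initial_conditions={sp.Symbol("x1"): 0, sp.Symbol("x2"): 1},
    )
    generic = si.oic_test(m, si.AnalysisOptions(seed=0))
    at_zero = si.oic_test(m, si.AnalysisOptions(seed=0, use_known_ic=True))
    assert generic.identifiable
    assert not at_zero.identifiable
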