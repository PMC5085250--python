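"""Model parsing, validation, augmentation and reparameterization."""

import pytest
import sympy as sp

import strucid as si
from strucid import ModelError
from strucid.model import parse_expression

from conftest import make_model

GOODWIN_DOC = """
name: mini
states: [x1, x2]
parameters: [k, d]
inputs: [u]
odes:
  - k*x2 - d*x1 + u
  - -x2
outputs: [x1]
initial_conditions: {x1: 0, x2: 1}
"""


def test_document_round_trip_preserves_symbols_and_expressions():
    m = si.loads_model(GOODWIN_DOC)
    m2 = si.loads_model(si.serialize(m))
    assert [s.name for s in m2.states] == ["x1", "x2"]
    assert [s.name for s in m2.parameters] == ["k", "d"]
    assert m2.odes == m.odes
    assert m2.outputs == m.outputs
    assert m2.initial_conditions == m.initial_conditions


@pytest.mark.parametrize("name", si.BENCHMARK_NAMES)
def test_bundled_models_round_trip(name):
    m = si.benchmark_model(name)
    m2 = si.loads_model(si.serialize(m))
    assert m2.states == m.states
    assert m2.parameters == m.parameters
    assert m2.odes == m.odes
    assert m2.outputs == m.outputs


def test_trigonometric_output_model_dimensions(angle_sensor):
    assert (angle_sensor.n, angle_sensor.m, angle_sensor.r) == (1, 2, 1)
    assert angle_sensor.outputs[0] == sp.cos(sp.Symbol("x"))


def test_submodel_document_with_pseudo_parameter():
    m = si.benchmark_model("arabidopsis_sub_x1x7")
    assert {s.name for s in m.states} == {"x1", "x7"}
    assert len(m.parameters) == 11
    assert "x6" in {p.name for p in m.parameters}
    assert m.outputs == (m.symbol("x1"),)


@pytest.mark.parametrize("doc, fragment", [
    (GOODWIN_DOC.replace("k*x2", "z*x2"), "undeclared"),
    (GOODWIN_DOC.replace("[k, d]", "[k, k]"), "more than once"),
    (GOODWIN_DOC.replace("  - -x2\n", ""), "ODEs"),
    (GOODWIN_DOC.replace("outputs: [x1]", "outputs: [x1*u]"), "inputs"),
])
def test_invalid_documents_are_rejected(doc, fragment):
    with pytest.raises(ModelError, match=fragment):
        si.loads_model(doc)


def test_parse_rejects_arbitrary_callables():
    with pytest.raises(ModelError):
        parse_expression("__import__('os')", {})


def test_augment_dimensions(goodwin, jakstat):
    assert si.augment(goodwin).dim == 11
    assert si.augment(jakstat).dim == 33
    plain = make_model("p", ["x"], [], [], ["-x"], ["x"])
    aug = si.augment(plain)
    assert aug.dim == plain.n
    assert aug.f_tilde == plain.odes


def test_augment_parameter_dynamics_are_zero(goodwin):
    aug = si.augment(goodwin)
    assert all(f == 0 for f in aug.f_tilde[goodwin.n:])
    assert aug.x_tilde[:goodwin.n] == goodwin.states
    assert aug.x_tilde[goodwin.n:] == goodwin.parameters


def test_reparameterize_identity(goodwin):
    assert si.reparameterize(goodwin, {}, {}) == goodwin


def test_reparameterize_counts(jakstat):
    th11 = jakstat.symbol("th11")
    th17, th22 = jakstat.symbol("th17"), jakstat.symbol("th22")
    m2 = si.reparameterize(
        jakstat,
        fix={th11: 1.0},
        substitute={(th17, th22): (sp.Symbol("Phi"), th17 * th22)},
    )
    # |x_tilde| = n + q - |fix| - (group size - 1)
    assert si.augment(m2).dim == 10 + 23 - 1 - 1
    assert sp.Symbol("Phi") in m2.parameters
    assert th17 not in m2.parameters and th22 not in m2.parameters


def test_reparameterize_fix_to_known_symbol(goodwin):
    b = goodwin.symbol("b")
    m2 = si.reparameterize(goodwin, fix={b: None})
    assert b in m2.known and b not in m2.parameters
    assert m2.q == goodwin.q - 1


def test_reparameterize_rejects_partial_combination():
    # p1 occurs both inside and outside the proposed combination p1*p2
    m = make_model("bad", ["x"], ["p1", "p2"], [],
                   ["p1*p2*x + p1*x**2"], ["x"])
    with pytest.raises(ModelError, match="outside the combination"):
        si.reparameterize(
            m, substitute={("p1", "p2"): (sp.Symbol("Phi"),
                                          sp.Symbol("p1") * sp.Symbol("p2"))}
        )
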