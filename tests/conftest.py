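import pytest
import sympy as sp

import strucid as si


@pytest.fixture
def opts():
    return si.AnalysisOptions(seed=1)


@pytest.fixture(scope="session")
def goodwin():
    return si.benchmark_model("goodwin")


@pytest.fixture(scope="session")
def jakstat():
    return si.benchmark_model("jakstat")


@pytest.fixture(scope="session")
def mapk():
    return si.benchmark_model("mapk")


def make_model(name, states, params, inputs, odes, outputs, **kw):
    """Build a model from strings without going through a document."""
    table = {}
    for nm in (*states, *params, *inputs, *kw.get("known", ())):
        table[nm] = sp.Symbol(nm)
    from strucid.model import parse_expression

    return si.Model(
        name=name,
        states=tuple(table[s] for s in states),
        parameters=tuple(table[p] for p in params),
        inputs=tuple(table[u] for u in inputs),
        odes=tuple(parse_expression(e, table) for e in odes),
        outputs=tuple(parse_expression(e, table) for e in outputs),
        known=tuple(table[k] for k in kw.get("known", ())),
        initial_conditions=kw.get("initial_conditions"),
    )


@pytest.fixture(scope="session")
def angle_sensor():
    """dx/dt = u measured through sin/cos: locally but not globally observable."""
    return make_model(
        "angle_sensor", ["x"], [], ["u"], ["u"], ["cos(x)", "sin(x)"]
    )


@pytest.fixture(scope="session")
def scale_toy():
    """dx/dt = 0, y = p*x: only the product p*x is determinable."""
    return make_model("scale_toy", ["x"], ["p"], [], ["0"], ["p*x"])
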