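"""Submodel induction, the VNS search, and merging of submodel verdicts."""

import pytest
import sympy as sp

import strucid as si
from strucid import IDENTIFIABLE

from conftest import make_model


@pytest.fixture(scope="module")
def arabidopsis():
    return si.benchmark_model("arabidopsis")


def test_induced_x1x7_submodel_matches_bundled_fixture(arabidopsis):
    sub = si.induce_submodel(arabidopsis, ["x1", "x7"])
    fixture = si.benchmark_model("arabidopsis_sub_x1x7")
    assert sub.feasible
    assert set(sub.model.parameters) == set(fixture.parameters)
    assert sub.pseudo_parameters == (arabidopsis.symbol("x6"),)
    assert sub.model.outputs == (arabidopsis.symbol("x1"),)
    assert sub.model.inputs == (arabidopsis.symbol("u"),)
    assert sub.selection == (1, 0, 0, 0, 0, 0, 1)
    assert sub.nd == 12


def test_full_subset_reproduces_parent(goodwin):
    sub = si.induce_submodel(goodwin, list(goodwin.states))
    assert sub.model.odes == goodwin.odes
    assert sub.model.outputs == goodwin.outputs
    assert sub.pseudo_parameters == ()


def test_output_less_subset_is_infeasible(goodwin):
    sub = si.induce_submodel(goodwin, ["x2"])
    assert not sub.feasible
    penalty = 10 * (goodwin.n + goodwin.q)
    assert si.submodel_cost(goodwin, sub.selection, max_states=3) >= penalty


def test_submodel_cost_values(goodwin, arabidopsis):
    assert si.submodel_cost(goodwin, (1, 1, 1), max_states=3) == \
        si.compute_nd(3, 8, 1)
    assert si.submodel_cost(arabidopsis, (1, 0, 0, 0, 0, 0, 1),
                            max_states=3) == 12
    # oversize penalty dominates any attainable n_d
    oversized = si.submodel_cost(arabidopsis, (1,) * 7, max_states=3)
    assert oversized > 10 * (arabidopsis.n + arabidopsis.q)


def test_vns_covers_every_state_and_dedups(goodwin, jakstat):
    for model in (goodwin, jakstat):
        opts = si.AnalysisOptions(seed=2, max_states_per_submodel=2,
                                  vns_shakes=8)
        subs = si.vns_decompose(model, opts)
        covered = set()
        seen = set()
        for sub in subs:
            covered |= set(sub.included_states)
            assert sub.selection not in seen
            seen.add(sub.selection)
        assert covered == set(model.states)


def test_merge_unions_identifiable_and_drops_pseudo(goodwin):
    opts = si.AnalysisOptions(seed=2, max_states_per_submodel=2,
                              vns_shakes=8)
    subs = si.vns_decompose(goodwin, opts)
    cls_list = si.analyze_submodels(goodwin, subs, opts)
    assert all(c.analysis_type == "PAI" for c in cls_list)
    merged = si.merge_results(cls_list)
    union = set()
    for c in cls_list:
        pseudo = set(c.provenance.submodel.pseudo_parameters)
        union |= {s for s, v in c.per_element.items()
                  if v == IDENTIFIABLE and s not in pseudo}
    assert merged.identifiable == union
    assert merged.analysis_type == "PAI"
    # pseudo-parameters never leak into the merged verdicts
    pseudo_all = set().union(
        *(set(c.provenance.submodel.pseudo_parameters) for c in cls_list)
    )
    assert not (set(merged.per_element) & pseudo_all - set(goodwin.states))


def test_merge_rejects_conflicting_parents(goodwin, jakstat, opts):
    a = si.analyze_submodels(
        goodwin, [si.induce_submodel(goodwin, ["x1"])], opts)
    b = si.analyze_submodels(
        jakstat, [si.induce_submodel(jakstat, ["x2"])], opts)
    with pytest.raises(ValueError, match="conflicting"):
        si.merge_results(a + b)


def test_identifiable_in_any_submodel_wins_the_merge(opts):
    # p is invisible in the x2-only submodel but identifiable from x1
    m = make_model("two_blocks", ["x1", "x2"], ["p"], [],
                   ["-p*x1", "-x2"], ["x1", "x2"])
    subs = [si.induce_submodel(m, ["x2"]), si.induce_submodel(m, ["x1"])]
    cls_list = si.analyze_submodels(m, subs, opts)
    merged = si.merge_results(cls_list)
    assert merged.per_element[m.symbol("p")] == IDENTIFIABLE


def test_submodel_conservativeness_on_goodwin_and_jakstat(goodwin, jakstat):
    """A parameter identifiable in a feasible submodel is identifiable in
    the full model (transfer property of the pseudo-parameter device)."""
    cases = [
        (goodwin, si.AnalysisOptions(seed=1, max_derivatives=9)),
        (jakstat, si.AnalysisOptions(seed=1)),
    ]
    for model, full_opts in cases:
        full = si.analyze_model(model, full_opts)
        full_ident = {
            s for s in model.parameters
            if full.rank_verdicts.get(s) == IDENTIFIABLE
        }
        opts = si.AnalysisOptions(seed=3, max_states_per_submodel=2,
                                  vns_shakes=6)
        subs = si.vns_decompose(model, opts)
        merged = si.merge_results(si.analyze_submodels(model, subs, opts))
        sub_ident = merged.identifiable & set(model.parameters)
        assert sub_ident <= full_ident
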