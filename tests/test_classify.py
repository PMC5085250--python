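"""Column-deletion classification, conclusiveness labels, refinement."""

import pytest
import sympy as sp

import strucid as si
from strucid import IDENTIFIABLE, INCONCLUSIVE, UNIDENTIFIABLE

from conftest import make_model


@pytest.fixture(scope="module")
def hidden_branch():
    """p2 drives an unmeasured dead-end state: zero column in OI."""
    return make_model(
        "hidden_branch", ["x1", "x2"], ["p1", "p2"], [],
        ["p1*x1", "p2 - x2"], ["x1"],
    )


def test_dead_end_parameter_and_state_are_unidentifiable(hidden_branch, opts):
    cls = si.analyze_model(hidden_branch, opts)
    assert cls.rank_verdicts[hidden_branch.symbol("p2")] == UNIDENTIFIABLE
    assert cls.rank_verdicts[hidden_branch.symbol("x2")] == UNIDENTIFIABLE
    assert cls.rank_verdicts[hidden_branch.symbol("p1")] == IDENTIFIABLE


def test_full_rank_classifies_everything_identifiable(opts):
    m = make_model("decay", ["x"], ["k"], [], ["-k*x"], ["x"])
    cls = si.analyze_model(m, opts)
    assert set(cls.per_element.values()) == {IDENTIFIABLE}
    assert cls.analysis_type == "CCA"


def test_identifiable_columns_are_independent(goodwin):
    """Deleting an identifiable column from a full-rank OI drops rank by 1,
    and the identifiable columns of a deficient OI are jointly independent."""
    opts = si.AnalysisOptions(seed=1, max_derivatives=9)
    aug = si.augment(goodwin)
    oi = si.build_oi(aug, opts)
    cls = si.classify_elements(oi, aug)
    full = oi.rank()
    ident_idx = {
        j for j, s in enumerate(oi.columns)
        if cls.rank_verdicts[s] == IDENTIFIABLE
    }
    for j, s in enumerate(oi.columns):
        drop = full - oi.rank_without(j)
        assert drop in (0, 1)
        assert (drop == 1) == (j in ident_idx)
    # joint independence of the identifiable columns
    from strucid.series import matrix_rank_rows
    kept = sorted(ident_idx)
    sub_rank = max(
        matrix_rank_rows([[row[j] for j in kept] for row in t.rows])
        for t in oi.trials
    )
    assert sub_rank == len(kept)


def test_partial_build_downgrades_unidentifiable_to_inconclusive(goodwin):
    opts = si.AnalysisOptions(seed=1, max_derivatives=9)
    cls = si.analyze_model(goodwin, opts)
    assert cls.analysis_type == "PAI"
    assert cls.unidentifiable == set()
    assert {s.name for s in cls.identifiable} >= {"b", "beta", "delta", "sigma"}


def test_refinement_completes_the_goodwin_diagnosis(goodwin):
    opts = si.AnalysisOptions(seed=1, max_derivatives=9)
    prior = si.analyze_model(goodwin, opts)
    found = {p for p in goodwin.parameters
             if prior.per_element.get(p) == IDENTIFIABLE}
    refined = si.iterative_refinement(goodwin, found, opts, prior=prior)
    assert refined.analysis_type == "CCA"
    assert {s.name for s in refined.unidentifiable
            if s in set(goodwin.parameters)} == {"a", "A", "alpha", "gamma"}
    # soundness: rank of the reduced system = original rank - removed columns
    assert refined.provenance.rank == prior.provenance.rank - len(found)


def test_refinement_of_empty_set_is_identity(hidden_branch, opts):
    base = si.analyze_model(hidden_branch, opts)
    same = si.iterative_refinement(hidden_branch, set(), opts, prior=base)
    assert same.per_element == base.per_element
    assert same.analysis_type == base.analysis_type


def test_refinement_refuses_states(goodwin, opts):
    with pytest.raises(ValueError, match="states"):
        si.iterative_refinement(goodwin, {goodwin.symbol("x1")}, opts)


def test_removing_unassessed_parameters_gives_pau(hidden_branch, opts):
    base = si.analyze_model(hidden_branch, opts)
    # p2 was never classified identifiable: removing it leaves only
    # unidentifiability conclusions trustworthy
    cls = si.iterative_refinement(
        hidden_branch, {hidden_branch.symbol("p2")}, opts, prior=base
    )
    assert cls.analysis_type == "PAU"
    assert cls.identifiable == set()


def test_variant_superset_outputs_is_pau(goodwin, opts):
    cls = si.variant_outputs_analysis(goodwin, ["x1", "x2", "x3"], opts)
    assert cls.analysis_type == "PAU"
    # the rank test itself reaches full rank: raw verdicts all identifiable,
    # but identifiability claims about the 1-output model are inconclusive
    assert set(cls.rank_verdicts.values()) == {IDENTIFIABLE}
    assert cls.identifiable == set()
    assert all(v == INCONCLUSIVE for v in cls.per_element.values())


def test_variant_subset_outputs_keeps_normal_semantics(mapk, opts):
    cls = si.variant_outputs_analysis(mapk, ["x1", "x2"], opts)
    assert cls.analysis_type == "CCA"
    assert {s.name for s in cls.unidentifiable
            if s in set(mapk.parameters)} == {"K1", "K2", "s3t"}


def test_variant_empty_outputs_rejected(goodwin, opts):
    with pytest.raises(ValueError):
        si.variant_outputs_analysis(goodwin, [], opts)
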