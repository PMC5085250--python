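"""Per-element classification by column deletion, and its conclusiveness.

Each column of the OI matrix is the sensitivity of the output derivatives
to one element of ``x_tilde``.  If deleting column ``i`` does not change
the rank, element ``i`` contributes nothing independent to the outputs: a
state is then locally unobservable, a parameter locally unidentifiable.
If the rank drops, the element is observable/identifiable.

Whether those verdicts are *conclusive* depends on how the matrix was
built:

* CCA (complete case analysis): full model, and either the rank stalled or
  the maximal order was reached — every verdict is conclusive.
* PAI (partial analysis for identifiability): fewer derivatives than the
  rank needed while the rank was still rising, or a submodel analysis —
  only "identifiable" verdicts are conclusive; "unidentifiable" is
  downgraded to inconclusive.
* PAU (partial analysis for unidentifiability): parameters of unassessed
  status were removed beforehand, or more outputs than are actually
  measured were assumed — only "unidentifiable" verdicts are conclusive.

``per_element`` always honours these downgrades; the raw column-test
outcomes remain available in ``rank_verdicts``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import sympy as sp

from .lie import OIMatrix, build_oi, compute_nd
from .model import AnalysisOptions, Model, augment, reparameterize

__all__ = [
    "IDENTIFIABLE",
    "UNIDENTIFIABLE",
    "INCONCLUSIVE",
    "Classification",
    "AnalysisContext",
    "classify_elements",
    "analyze_model",
    "iterative_refinement",
    "variant_outputs_analysis",
]

IDENTIFIABLE = "identifiable_or_observable"
UNIDENTIFIABLE = "unidentifiable_or_unobservable"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class AnalysisContext:
    """How the OI matrix under classification came to be."""

    submodel: object | None = None          # decompose.Submodel if any
    removed_unassessed: frozenset = frozenset()
    extra_outputs: bool = False
    removed_identifiable: frozenset = frozenset()


@dataclass
class Provenance:
    orders_used: int = 0
    rank: int = 0
    full_rank_needed: int = 0
    nd: int = 0
    stop_reason: str | None = None
    mode: str = "numeric"
    trials: int = 1
    seed: int = 0
    outputs_used: tuple = ()
    submodel: object | None = None
    removed_parameters: tuple = ()


@dataclass
class Classification:
    """Per-element verdicts plus the type of analysis that produced them."""

    per_element: dict[sp.Symbol, str]
    analysis_type: str                     # 'CCA' | 'PAI' | 'PAU'
    rank_verdicts: dict[sp.Symbol, str]    # raw column-test outcomes
    provenance: Provenance
    parent: str = ""

    def elements(self, verdict: str, parameters_only: bool = False,
                 model: Model | None = None) -> set[sp.Symbol]:
        chosen = {s for s, v in self.per_element.items() if v == verdict}
        if parameters_only and model is not None:
            chosen &= set(model.parameters)
        return chosen

    @property
    def identifiable(self) -> set[sp.Symbol]:
        return self.elements(IDENTIFIABLE)

    @property
    def unidentifiable(self) -> set[sp.Symbol]:
        return self.elements(UNIDENTIFIABLE)

    @property
    def inconclusive(self) -> set[sp.Symbol]:
        return self.elements(INCONCLUSIVE)

    def merged_with_prior(self, prior_identifiable: dict) -> "Classification":
        per = dict(self.per_element)
        raw = dict(self.rank_verdicts)
        for s in prior_identifiable:
            per[s] = IDENTIFIABLE
            raw[s] = IDENTIFIABLE
        return dc_replace(self, per_element=per, rank_verdicts=raw)


def _analysis_type(oi: OIMatrix, context: AnalysisContext) -> str:
    if context.removed_unassessed or context.extra_outputs:
        return "PAU"
    if context.submodel is not None:
        return "PAI"
    if not oi.complete:
        return "PAI"
    return "CCA"


def classify_elements(
    oi: OIMatrix,
    aug=None,
    context: AnalysisContext | None = None,
) -> Classification:
    """Column-deletion classification of every state and parameter.

    Deletion ranks are computed in the same mode, with the same trials and
    evaluation points, as the parent rank; when numeric trials disagree the
    maximum rank is used (generic-rank semantics).
    """
    aug = aug or oi.model
    context = context or AnalysisContext()
    full = oi.rank()
    raw: dict[sp.Symbol, str] = {}
    if full == oi.full_rank_needed:
        for s in oi.columns:
            raw[s] = IDENTIFIABLE
    else:
        for j, s in enumerate(oi.columns):
            dropped = oi.rank_without(j)
            raw[s] = UNIDENTIFIABLE if dropped == full else IDENTIFIABLE

    a_type = _analysis_type(oi, context)
    per = dict(raw)
    if a_type == "PAI":
        for s, v in per.items():
            if v == UNIDENTIFIABLE:
                per[s] = INCONCLUSIVE
    elif a_type == "PAU":
        for s, v in per.items():
            if v == IDENTIFIABLE:
                per[s] = INCONCLUSIVE

    opts = oi.opts or AnalysisOptions()
    base = aug.base
    prov = Provenance(
        orders_used=oi.order_built,
        rank=full,
        full_rank_needed=oi.full_rank_needed,
        nd=compute_nd(base.n, base.q, base.m),
        stop_reason=oi.stop_reason,
        mode=oi.mode,
        trials=len(oi.trials) if oi.mode == "numeric" else 1,
        seed=opts.seed,
        outputs_used=tuple(base.outputs),
        submodel=context.submodel,
        removed_parameters=tuple(sorted(
            (s.name for s in context.removed_identifiable |
             context.removed_unassessed))),
    )
    parent = (
        context.submodel.parent if context.submodel is not None else base.name
    )
    return Classification(
        per_element=per, analysis_type=a_type, rank_verdicts=raw,
        provenance=prov, parent=parent,
    )


def analyze_model(
    model: Model,
    opts: AnalysisOptions | None = None,
    context: AnalysisContext | None = None,
) -> Classification:
    """Augment, build OI and classify in one step."""
    opts = opts or AnalysisOptions()
    aug = augment(model)
    oi = build_oi(aug, opts)
    return classify_elements(oi, aug, context)


# ---------------------------------------------------------------------------
# Iterative refinement
# ---------------------------------------------------------------------------

def iterative_refinement(
    model: Model,
    known_identifiable,
    opts: AnalysisOptions | None = None,
    prior: Classification | None = None,
) -> Classification:
    """Re-run the analysis after removing already-identified parameters.

    Because parameters have trivial dynamics, removing an identifiable
    parameter from the augmented vector leaves a matrix whose rank equals
    the original rank minus the removed columns, so verdicts on the
    remaining elements are unchanged while the problem shrinks.  The same
    is NOT true of states (their dynamics are not zero), so removing states
    is refused.

    If a removed parameter was never classified identifiable (checked
    against ``prior`` when given), only unidentifiability conclusions remain
    trustworthy and the result is downgraded to a PAU.
    """
    opts = opts or AnalysisOptions()
    removed = {
        model.symbol(s) if isinstance(s, str) else s
        for s in known_identifiable
    }
    bad_states = removed & set(model.states)
    if bad_states:
        raise ValueError(
            f"cannot remove states {sorted(s.name for s in bad_states)}: "
            "refinement applies only to parameters (states have dx/dt != 0)"
        )
    not_params = removed - set(model.parameters)
    if not_params:
        raise ValueError(
            f"{sorted(s.name for s in not_params)} are not parameters of {model.name}"
        )

    unassessed: set[sp.Symbol] = set()
    if prior is not None:
        unassessed = {
            s for s in removed if prior.per_element.get(s) != IDENTIFIABLE
        }

    reduced = reparameterize(model, fix={s: None for s in removed})
    context = AnalysisContext(
        removed_identifiable=frozenset(removed - unassessed),
        removed_unassessed=frozenset(unassessed),
    )
    cls = analyze_model(reduced, opts, context)
    if not unassessed:
        cls = cls.merged_with_prior({s: IDENTIFIABLE for s in removed})
    return cls


# ---------------------------------------------------------------------------
# Variant output sets
# ---------------------------------------------------------------------------

def variant_outputs_analysis(
    model: Model,
    outputs,
    opts: AnalysisOptions | None = None,
) -> Classification:
    """Re-run the analysis with a modified output set.

    When the requested outputs are a proper superset of what the model
    actually measures, "identifiable" verdicts describe a hypothetical
    better-instrumented experiment and are therefore inconclusive for the
    model as it stands (PAU); unidentifiability, however, transfers.  With
    the model's own outputs (or a subset, i.e. a degraded measurement
    scenario analysed in its own right), normal semantics apply.
    """
    opts = opts or AnalysisOptions()
    table = {
        s.name: s
        for s in (*model.states, *model.parameters, *model.known)
    }
    from .model import parse_expression

    exprs = tuple(
        parse_expression(o, table) if isinstance(o, str) else sp.sympify(o)
        for o in outputs
    )
    if not exprs:
        raise ValueError("empty output set")
    variant = model.with_outputs(exprs)
    original = set(model.outputs)
    superset = original < set(exprs)
    return analyze_model(
        variant, opts, AnalysisContext(extra_outputs=superset)
    )
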