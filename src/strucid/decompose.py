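"""Decomposition of large models into analyzable submodels.

A submodel keeps a subset of the states together with their original
equations; the outputs are those of the parent that involve a retained
state, and any excluded state referenced by the retained equations or
outputs is treated as an *unknown constant parameter* (a pseudo-parameter).
Treating excluded states as unknown constants — rather than as inputs — is
conservative: a parameter found identifiable in such a submodel is
identifiable in the parent model too, so submodel analyses are PAIs whose
identifiable verdicts transfer.

Submodels are chosen either explicitly or by minimising the number of Lie
derivatives the submodel needs, ``n_d = ceil((n+q)/m - 1)``, over the
binary inclusion vector ``s`` with a Variable Neighbourhood Search:
``n`` seeded runs (run ``j`` forces state ``j`` in, so every state — and
hence every parameter — is eventually covered), each alternating shaking
at growing Hamming radius with first-improvement single-flip descent.
Oversized and output-less subsets are penalised.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import sympy as sp

from .classify import (
    IDENTIFIABLE,
    INCONCLUSIVE,
    AnalysisContext,
    Classification,
    Provenance,
    analyze_model,
)
from .lie import compute_nd
from .model import AnalysisOptions, Model

__all__ = [
    "Submodel",
    "induce_submodel",
    "submodel_cost",
    "vns_decompose",
    "merge_results",
    "analyze_submodels",
]


@dataclass
class Submodel:
    """A subsystem induced by a subset of the parent's states."""

    parent: str
    model: Model | None
    included_states: tuple[sp.Symbol, ...]
    pseudo_parameters: tuple[sp.Symbol, ...]
    selection: tuple[int, ...]
    feasible: bool
    cost: float | None = None

    @property
    def nd(self) -> int | None:
        if not self.feasible:
            return None
        return compute_nd(self.model.n, self.model.q, self.model.m)


def induce_submodel(model: Model, subset) -> Submodel:
    """Restrict the model to ``subset`` of its states.

    Excluded states that appear in the retained equations or outputs become
    pseudo-parameters: ordinary parameters tagged (by listing) with the
    state they stand for.  A subset whose induced output set is empty is
    infeasible (flagged, not an error).
    """
    subset_syms = [
        model.symbol(s) if isinstance(s, str) else s for s in subset
    ]
    if not subset_syms:
        raise ValueError("submodel state subset must be nonempty")
    order = {s: i for i, s in enumerate(model.states)}
    included = tuple(sorted(set(subset_syms), key=order.__getitem__))
    inc_set = set(included)
    excluded = [s for s in model.states if s not in inc_set]

    odes = tuple(
        model.odes[order[s]] for s in included
    )
    outputs = tuple(
        g for g in model.outputs if g.free_symbols & inc_set
    )
    selection = tuple(1 if s in inc_set else 0 for s in model.states)
    if not outputs:
        return Submodel(
            parent=model.name, model=None, included_states=included,
            pseudo_parameters=(), selection=selection, feasible=False,
        )

    used: set[sp.Symbol] = set()
    for e in (*odes, *outputs):
        used |= e.free_symbols
    params = tuple(p for p in model.parameters if p in used)
    pseudo = tuple(s for s in excluded if s in used)
    inputs = tuple(u for u in model.inputs if u in used)
    known = tuple(k for k in model.known if k in used)

    sub = Model(
        name=f"{model.name}[{','.join(s.name for s in included)}]",
        states=included,
        parameters=params + pseudo,
        inputs=inputs,
        odes=odes,
        outputs=outputs,
        known=known,
        initial_conditions=None,
    )
    return Submodel(
        parent=model.name, model=sub, included_states=included,
        pseudo_parameters=pseudo, selection=selection, feasible=True,
    )


def submodel_cost(
    model: Model, selection, max_states: int | None = None
) -> float:
    """VNS objective: the submodel's ``n_d`` plus constraint penalties.

    The penalty, ``10 * (n + q)`` of the parent per violated constraint,
    dominates any attainable ``n_d``.
    """
    selection = tuple(int(b) for b in selection)
    if len(selection) != model.n:
        raise ValueError("selection vector length must equal n")
    penalty_unit = 10 * (model.n + model.q)
    subset = [s for s, b in zip(model.states, selection) if b]
    cost = 0.0
    if not subset:
        return 2 * penalty_unit
    sub = induce_submodel(model, subset)
    if not sub.feasible:
        cost += penalty_unit
        nd = compute_nd(len(subset), 0, 1)
    else:
        nd = sub.nd
    if max_states is not None and len(subset) > max_states:
        cost += penalty_unit
    return cost + nd


def vns_decompose(
    model: Model, opts: AnalysisOptions | None = None
) -> list[Submodel]:
    """Find low-``n_d`` submodels by Variable Neighbourhood Search.

    One optimization per state, forcing that state into the solution, so
    the union of the returned subsets covers every state.  Neighbourhoods
    are Hamming balls explored by random k-bit shaking (k cycling
    1..k_max) followed by first-improvement single-flip descent.  Results
    are deduplicated keeping the lowest-cost instance of each subset.
    """
    opts = opts or AnalysisOptions()
    if model.n < 2:
        sub = induce_submodel(model, list(model.states))
        sub.cost = submodel_cost(model, sub.selection,
                                 opts.max_states_per_submodel)
        return [sub]
    n = model.n
    k_max = min(n, 5)
    max_states = opts.max_states_per_submodel
    results: dict[tuple[int, ...], Submodel] = {}

    def cost_of(sel):
        return submodel_cost(model, sel, max_states)

    for j in range(n):
        rng = random.Random(opts.seed * 100003 + j)
        cur = [0] * n
        cur[j] = 1
        cur_cost = cost_of(cur)
        best, best_cost = list(cur), cur_cost
        k = 1
        for _ in range(opts.vns_shakes):
            cand = list(best)
            flips = rng.sample([i for i in range(n) if i != j],
                               min(k, n - 1))
            for i in flips:
                cand[i] ^= 1
            cand_cost = cost_of(cand)
            # first-improvement single-flip descent
            improved = True
            while improved:
                improved = False
                for i in range(n):
                    if i == j:
                        continue
                    cand[i] ^= 1
                    c = cost_of(cand)
                    if c < cand_cost:
                        cand_cost = c
                        improved = True
                        break
                    cand[i] ^= 1
            if cand_cost < best_cost:
                best, best_cost = cand, cand_cost
                k = 1
            else:
                k = k % k_max + 1
        sub = induce_submodel(
            model, [s for s, b in zip(model.states, best) if b]
        )
        sub.cost = best_cost
        key = tuple(best)
        if key not in results or results[key].cost > best_cost:
            results[key] = sub
    return list(results.values())


def analyze_submodels(
    model: Model,
    submodels: list[Submodel],
    opts: AnalysisOptions | None = None,
) -> list[Classification]:
    """Run the rank analysis on each feasible submodel (PAI semantics)."""
    opts = opts or AnalysisOptions()
    out = []
    for sub in submodels:
        if not sub.feasible:
            continue
        cls = analyze_model(
            sub.model, opts, AnalysisContext(submodel=sub)
        )
        out.append(cls)
    return out


def merge_results(classifications: list[Classification]) -> Classification:
    """Union of identifiable verdicts across submodel analyses.

    Only identifiability transfers from a submodel to the parent
    (conservativeness of the pseudo-parameter construction);
    unidentifiability in a submodel is inconclusive for the parent.
    Pseudo-parameter verdicts are discarded.
    """
    if not classifications:
        raise ValueError("nothing to merge")
    parents = {c.parent for c in classifications}
    if len(parents) != 1:
        raise ValueError(f"conflicting parent models: {sorted(parents)}")

    per: dict[sp.Symbol, str] = {}
    for cls in classifications:
        sub = cls.provenance.submodel
        pseudo = set(sub.pseudo_parameters) if sub is not None else set()
        for s, v in cls.per_element.items():
            if s in pseudo:
                continue
            if v == IDENTIFIABLE:
                per[s] = IDENTIFIABLE
            else:
                per.setdefault(s, INCONCLUSIVE)
    prov = Provenance(
        stop_reason="merged",
        mode=classifications[0].provenance.mode,
        trials=classifications[0].provenance.trials,
        seed=classifications[0].provenance.seed,
    )
    return Classification(
        per_element=per,
        analysis_type="PAI",
        rank_verdicts=dict(per),
        provenance=prov,
        parent=classifications[0].parent,
    )
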