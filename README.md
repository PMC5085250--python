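# strucid

Local structural identifiability and observability analysis of nonlinear
ODE models, for modellers in systems biology and beyond who need to know
— *before* fitting — which parameters of a model can in principle be
estimated from the planned measurements, which cannot, and what to do
about the ones that cannot.

## The method

For a model

    dx/dt = f(x, u, p),    y = g(x, p),

with states `x ∈ Rⁿ`, unknown parameters `p ∈ R^q`, inputs `u` and
outputs `y ∈ R^m` (`f`, `g` analytic — Hill and lin-log kinetics,
trigonometric terms and unknown exponents are all fine), the parameters
are adjoined to the state as `x̃ = [x, p]` with `dp/dt = 0`.  Stacking
the Jacobians of the Lie derivatives `L_f^i g` with respect to `x̃`
yields the observability–identifiability matrix `OI(x̃)`; if
`rank OI = n + q` at a generic point, the model is locally observable
and all parameters are locally structurally identifiable.  The first
order at which full rank is possible is `n_d = ⌈(n+q)/m − 1⌉`, and
orders above `n + q − 1` never help, which brackets the computation.

When the rank is deficient the package:

* classifies every state and parameter by **column deletion** (rank
  unchanged after deleting a column ⇒ that element is unobservable /
  unidentifiable), with conclusiveness labels (complete vs. partial
  analyses) tracking how the matrix was built;
* finds **identifiable combinations** of unidentifiable parameters from
  the null space of the reduced matrix `O_U`, solving the associated
  first-order PDE by characteristics (e.g. products `p_i·p_j`, sums
  `p_i + p_j`);
* **decomposes** large models into submodels (excluded states become
  unknown-constant pseudo-parameters, so submodel identifiability
  transfers to the parent), found by a seeded Variable Neighbourhood
  Search minimising the submodel's `n_d`;
* **refines iteratively**: parameters already established identifiable
  are treated as known and the smaller system is re-analysed.

Ranks are computed either symbolically (exact, small models) or — the
default — by exact evaluation at random prime-valued points, propagated
through a Taylor-series/dual-number scheme that never forms the huge
symbolic entries.  Several independent trials are taken and the maximum
rank reported, so specialisation can only err on the conservative side.
See `docs/methods.md` for the full account.

## A worked example

The Goodwin oscillator — a classic transcriptional-repression loop with
Hill nonlinearity of unknown exponent, 3 states, 8 parameters, only the
enzyme concentration `x1` measured — ships as a bundled model:

```python
import strucid as si

model = si.benchmark_model("goodwin")
report = si.run_analysis(
    model, si.AnalysisOptions(seed=1, max_derivatives=9)
)
print(report.to_text())
```

prints

```
Model goodwin: n=3 states, q=8 parameters, r=0 inputs, m=1 outputs (n_d = 10)
Verdict: structurally unidentifiable  [CCA]

element       kind       verdict
x1            state      identifiable/observable
x2            state      unidentifiable/unobservable
x3            state      unidentifiable/unobservable
a             parameter  unidentifiable/unobservable
A             parameter  unidentifiable/unobservable
alpha         parameter  unidentifiable/unobservable
b             parameter  identifiable/observable
beta          parameter  identifiable/observable
gamma         parameter  unidentifiable/unobservable
delta         parameter  identifiable/observable
sigma         parameter  identifiable/observable

Rank trace (order, rows, rank, seconds):
    9    10     9 0.557
```

Reading this: full rank would need 10 Lie derivatives (`n_d = 10`), but
a 9-derivative matrix already proves `b`, `β`, `δ` and `σ` identifiable
(their columns drop the rank when deleted).  The workflow then removes
those four and re-analyses the smaller system, which *completes* the
diagnosis (hence `CCA`): the remaining four parameters `a`, `A`, `α`,
`γ` are structurally unidentifiable — half of this small model cannot be
estimated from `x1` alone, no matter how good the data.  Measuring all
three states instead makes every parameter identifiable
(`si.variant_outputs_analysis(model, ["x1","x2","x3"], ...)`).

The same API drives the other bundled case studies (NF-κB, JAK/STAT,
MAPK, drug uptake, the Arabidopsis circadian clock — see
`strucid.BENCHMARK_NAMES` and the file docstrings under
`strucid/models/`, two of which are labelled synthetic surrogates).  For
the JAK/STAT model the combination search returns `Φ = th17·th22` with
kernel vector `[0, 0, −th17/th22, 0, 1]`, and reparameterizing with `Φ`
plus fixing `th11` produces a fully identifiable 21-parameter model.

A command-line interface wraps the library:

```
strucid analyze --model model.yaml --seed 1 --json report.json
strucid nd --model model.yaml
strucid decompose --model model.yaml --max-states 3
strucid combos --model model.yaml
strucid report --report report.json
```

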