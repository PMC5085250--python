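# Methods

## Model class and problem statement

`strucid` analyses dynamic models

    dx/dt = f(x(t), u(t), p),      y(t) = g(x(t), p),      x(0) = x0,

with `n` states, `q` unknown parameters, `r` known inputs and `m` measured
outputs, where `f` and `g` are analytic in the declared symbols.  The
supported expression grammar — field operations, integer and symbolic real
powers, `exp`, `log`, `sin`, `cos` — covers mass-action, Michaelis–Menten,
Hill (including unknown Hill exponents) and lin-log kinetics as well as
trigonometric mechanics; rationality is *not* required.  Outputs may not
depend on the inputs directly.

A parameter is locally structurally identifiable if, for almost every
parameter point, no other point in a neighbourhood produces identical
output trajectories.  The package treats this as observability of the
augmented state `x̃ = [x, p]` in which parameters are states with
`dp/dt = 0`: stacking the Jacobians of the Lie derivatives
`L_f^i g` (i = 0, 1, …) with respect to `x̃` gives the
observability–identifiability matrix `OI`, and `rank OI = n + q` at a
generic point is sufficient for local observability plus identifiability.
All conclusions are local; a model such as `dx/dt = u`,
`y = (cos x, sin x)` passes the rank test yet is globally
indistinguishable from translates by `2πk`, and the package makes no
global claims.

Two a-priori bounds bracket the recursion: full rank is impossible before
order `n_d = ⌈(n+q)/m − 1⌉`, and orders beyond `n + q − 1` can never
increase the rank.  Within the bracket the build stops as soon as the
rank stalls, since a stalled rank never grows again.

## Rank evaluation

**Symbolic mode** computes the exact generic rank of the symbolic matrix
(fraction-field elimination where the entries are rational functions,
simplification-based elimination otherwise).  It is the reference oracle
but is only affordable for small systems: the entries roughly double in
size per Lie order.

**Numeric mode** (default) evaluates `rank OI` at random points with every
symbol replaced by a distinct prime, in exact arithmetic.  Rather than
building the symbolic entries and substituting, the engine uses the
identity `L_f^i g = dⁱ/dtⁱ g(x(t))` along the flow: the trajectory is
propagated as a truncated Taylor series in `t` whose coefficients are
first-order dual numbers carrying sensitivities with respect to `x̃`.
Row block `i` of `OI` at the point is `i!` times the gradient of the
`i`-th Taylor coefficient of `y`.  The result equals prime substitution
into the symbolic matrix, at polynomial cost in the order.  Details that
matter:

* **Transcendental constants.**  `log`, `exp`, `sin`/`cos` of a rational
  point value, or a non-integer power, produce constants algebraically
  independent of the rationals.  They are replaced by fresh random
  rational surrogates per trial; a sine/cosine pair shares a random
  rational point on the unit circle so `sin² + cos² = 1` is preserved.
* **Coefficient domain.**  By default each trial works in `GF(p)` for a
  random 62-bit prime `p` (`numeric_domain="gf"`); exact rationals are
  available with `numeric_domain="rational"`.  Every layer of
  specialisation — the point, the surrogates, the reduction mod `p` —
  can only *lower* a generic rank, never raise it, so the maximum rank
  over `numeric_trials` independent trials (default 3) is a certified
  lower bound that equals the generic rank outside a measure-zero set of
  draws.  No floating-point rank tolerance is involved anywhere.
* **Prime sizes.**  Symbols appearing inside exponents (Hill
  coefficients) draw small primes (2–13) so that integer powers stay
  tractable; all other symbols draw the smallest primes above 13.
  Degenerate draws that hit a pole raise an error and are resampled
  (up to five times) — except in known-initial-condition mode, where a
  pole at the supplied `x0` is a genuine property of the model and is
  reported.
* **Inputs.**  Inputs are held symbolic (numerically: generic constants).
  With `input_derivative_order = d > 0` they are treated as analytic time
  functions with free derivatives up to order `d` (symbolically: a chain
  of primed symbols; numerically: a random truncated Taylor series).

The per-derivative wall-clock budget `max_lie_seconds` (default 100 s)
stops the build after any order that exceeded it; a breach is a recorded
outcome consumed by the decomposition policy, never an exception.

## Classification and conclusiveness

Column `i` of `OI` is the sensitivity of the output derivatives to
element `i` of `x̃`.  If deleting it leaves the rank unchanged, the
element is locally unobservable/unidentifiable; if the rank drops, it is
observable/identifiable.  Deletion ranks reuse the parent's mode, trials
and evaluation points; when trials disagree, the maximum rank wins
(generic-rank semantics).

Conclusiveness follows from how the matrix was built.  A full-model build
that stalled or reached the order cap is a complete case analysis (CCA).
A build truncated while the rank was still rising, or any submodel
analysis, is a partial analysis for identifiability (PAI): only
"identifiable" verdicts are conclusive, and the classification downgrades
the rest to "inconclusive" automatically.  Removing parameters of
unassessed status, or assuming more outputs than the model measures, is a
partial analysis for unidentifiability (PAU): only "unidentifiable"
verdicts are conclusive.  `Classification.per_element` always honours
these downgrades; the raw column-test outcomes remain in
`rank_verdicts` (used, e.g., to report that a *better-instrumented*
variant of the model would be identifiable even though that statement is
PAU-inconclusive for the model as it stands).

**Iterative refinement.**  Parameters established identifiable are moved
to the model's `known` set (still symbolic, hence still generic — they
are not given numeric values) and the smaller system is re-analysed; the
reduced matrix is the original with the corresponding columns removed, so
remaining verdicts are unchanged while cost drops.  The workflow repeats
this until no new verdicts appear.  States cannot be removed this way
(their dynamics are not zero) and the API refuses them.

## Identifiable combinations

On a rank-deficient system the columns of the unidentifiable parameters
form the reduced matrix `O_U`; each right null-space vector `v` defines
the PDE `Σ v_i ∂Φ/∂p_i = 0` whose first integrals are identifiable
combinations.  The solver is pattern-based by design: two-entry vectors
with constant or separable-monomial coefficient ratios integrate in
closed form (linear combinations, products, ratios, powers), and
everything else is returned as an unsolved PDE.  Null vectors that
involve state columns describe state–parameter symmetries and are
reported unsolved.  Every solved `Φ` is verified by substitution into its
PDE before being reported.

The kernel itself is symbolic, but no symbolic ranks are ever computed:
the classification comes from the numeric analysis, a maximal independent
row subset of `O_U` is located numerically, the null space of that small
submatrix is computed symbolically, and the resulting vectors are
verified against every built symbolic row.  The symbolic blocks are built
only up to the smallest order at which `O_U` reaches its final column
rank (equal rank on nested row sets implies equal row space, hence equal
null space); the order is read off the stored numeric trials.

## Decomposition

A submodel keeps a state subset with its original equations; parent
outputs involving a kept state are kept, and any excluded state that the
retained equations or outputs reference becomes a *pseudo-parameter* — an
unknown constant.  This is deliberately conservative: an unknown constant
carries less excitation than the true time course, so identifiability
established in the submodel transfers to the parent (the converse does
not hold, which is why submodel analyses are PAIs and `merge_results`
unions only the identifiable verdicts, discarding pseudo-parameters).

Subsets are chosen by minimising the submodel's `n_d` over the binary
inclusion vector with a Variable Neighbourhood Search: one run per state
`j` with `s_j` forced to 1 (so the union of results covers every state
and hence eventually every parameter), shaking at Hamming radius `k`
cycling `1..min(n, 5)`, first-improvement single-bit descent, a budget of
`vns_shakes` shake-descend cycles per run (default 40), and a penalty of
`10·(n+q)` per violated constraint (oversize, or no induced output) which
dominates any attainable `n_d`.  Identical subsets are deduplicated
keeping the lowest cost.  The search is seeded and its trace (subset,
cost, `n_d`, pseudo-parameters) is embedded in the report.

## Workflow

`run_analysis` chains the pieces: full-model build (unless
`decompose_policy="always"`); on a budget breach either the partial
matrix is classified (PAI) or the model is decomposed and the submodel
verdicts merged, per policy; iterative refinement absorbs every newly
identifiable parameter (up to `max_refinement_rounds`, default 4); if
unidentifiable parameters remain and `find_combinations` is set, the
combination search runs on the reduced model.  The report carries the
verdict table with conclusiveness labels, the per-order rank trace with
timings, the decomposition and refinement traces, the combinations with
their kernel vectors, and every option and seed needed to reproduce the
run; with a fixed seed the numeric-mode report is reproducible verbatim.

## Synthetic models with planted truth

The generator builds polynomial models whose identifiability structure is
known by construction: every non-planted parameter multiplies its own
monomial of measured states (identifiable); a planted product pair occurs
only as `p_i·p_j`, a planted sum pair only as `(p_i + p_j)` (the pair is
unidentifiable, the combination identifiable and recoverable by the
kernel solver); a planted disconnected state is unmeasured, feeds no
other state and owns three private parameters (state unobservable,
parameters unidentifiable).  Unmeasured connected states are chained
linearly into measured ones so they stay observable.  Before a model is
handed out, `verify=True` (the default) checks the claimed truth with the
exact-rational numeric analysis at three independent points;
`verify_mode="symbolic"` uses the symbolic engine instead, which is
affordable only at very small sizes (the Lie entries double in degree per
order, and exact symbolic elimination on the stacked Jacobians of even a
3-state, 5-parameter polynomial model exceeds desk scale).  These models
exercise the pipeline's bookkeeping and the combination solver; they are
deliberately *easier* than real kinetic models (polynomial, well-scaled,
no near-symmetries), so passing them demonstrates correctness of the
machinery, not robustness to modelling pathologies.

## Bundled case studies

Eight benchmark models ship as plain-text documents under
`strucid/models/` with dimensions and published verdicts recorded in
`strucid.EXPECTED`: the Goodwin oscillator (3/1/8 for states/outputs/
parameters), a hepatic drug-uptake pair (3/1/7 and 2/1/6), a three-layer
MAPK cascade with mixed feedback (3/3/14), the NF-κB pathway (15/6/29),
a JAK/STAT pathway (10/8/23), and the two-loop Arabidopsis circadian
clock (7/2/28) with its two-state `{x1, x7}` submodel.  The drug-uptake
pair and the JAK/STAT model are synthetic surrogates, labelled as such in
their files: they match the published dimensions and identifiability
structure (verdict sets, kernel vector, identifiable combination,
reparameterization outcome) but not necessarily the original rate laws.
The MAPK document is a reconstruction from the published description that
reproduces all published verdicts for that model.

## Numerical and design choices

* Column order is states-then-parameters, each in declaration order; all
  reported column indices refer to it.
* Initial conditions are metadata unless `use_known_ic` is set; the
  generic analysis treats `x0` as a generic symbolic point.
* Symbolic Lie derivatives are lightly simplified per order (common
  denominator + cancellation), skipped above 2000 expression nodes.
* `n_d` is implemented literally as `⌈(n+q)/m − 1⌉` (floored at 0).
  For the full Arabidopsis model (7, 28, 2) this gives 17.
* Ties between numeric trials always resolve to the maximum rank.
* Kernel vectors are normalised so the last nonzero entry is 1.
* The column-deletion book-keeping asserts, per fixture, that each
  deletion changes the rank by 0 or 1, that exactly the
  identifiable columns drop it, and that the identifiable columns are
  jointly independent (their submatrix has full column rank).

## Problem sizes used in the test suite

The suite analyses every bundled model in numeric mode: Goodwin at a
9-derivative cap plus refinement, the MAPK output-removal scenarios, the
JAK/STAT combination search and reparameterization closure, the complete
NF-κB case analysis, and a 2-state-budget decomposition of the
Arabidopsis model with 12 shake cycles per VNS run; synthetic recovery
runs 20 seeded models at n ≤ 4, q = 7, and the linear-system oracle
checks 50 random systems at n ≤ 4.  These sizes give a complete pass of
every code path while keeping the default run to a few minutes.

## Known limitations

* All verdicts are *local*; global identifiability is out of scope.
* The numeric mode is one-sided by construction: it can (with vanishing
  probability) under-report a rank, never over-report one; trials guard
  against this, and the symbolic mode is available as the exact check at
  small scale.
* The PDE solver handles the coefficient patterns that occur in the
  bundled and planted cases (constant and separable-monomial ratios for
  vector pairs); richer kernels are reported unsolved rather than risked.
* Decomposition can legitimately fail to classify every parameter; its
  output is a PAI by design.
* DAE, delay, stochastic and PDE models, time-varying parameters, and
  practical (data-driven) identifiability are out of scope.
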