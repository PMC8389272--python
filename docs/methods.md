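# Methods

## Model

A reaction scheme is a directed bipartite structure: species symbols and
reaction steps, connected by edges carrying stoichiometric coefficients.
Three constructs extend the plain network:

* **Layers.** Every element carries a layer label. Layers are unordered and
  non-hierarchical — they mirror how pathway diagrams are split by role,
  nothing more. All numerics operate on the flattened scheme; `flatten` is
  idempotent and preserves the multiset of (reaction, species, role,
  coefficient) edges, which is the invariant the test suite pins down.
* **Shortcut symbols.** A shortcut is a pointer to a species (never to
  another shortcut — chains are rejected by validation). Name,
  concentration and reactant type are read through the pointer, so an edit
  to the target is immediately visible through every shortcut; only the
  stoichiometric coefficient is stored locally. During derivation a
  shortcut edge contributes to its *target's* mass balance using the
  *shortcut's* coefficient. Because coefficients live on the wired symbol
  (or an explicit per-edge override), one species can be consumed with
  coefficient 2 in one reaction and 1 in another — the behaviour the
  ATP/ADP and butanol fixtures exercise.
* **Pools, rules, events.** A species is either a state variable or a
  constant pool (boundary condition). Assignment-rule targets are computed
  outputs: they are excluded from the ODE state, must have zero net
  stoichiometry (enforced at derivation), must form an acyclic dependency
  graph, and are evaluated in topological order wherever rates, triggers
  or outputs need them. Events fire on a false→true transition of their
  trigger.

### Identifier policy

Display names are unrestricted ("NAD+", "1,3-diphosphoglycerate");
identifiers must be valid in expressions and SBML. `sanitize_id` replaces
non-alphanumerics with `_`, prefixes a leading digit with `_`, suffixes
reserved words (`t`, function names, `and/or/not`), and de-duplicates with
numeric suffixes. Reaction-local kinetic parameters are namespaced
`reactionid__name` in the derived parameter table so they can coexist and
be addressed by the estimator.

## Expression language

Kinetic laws, rules and triggers share one grammar: `+ - * / ^` (with `^`
right-associative and binding tighter than unary minus), comparisons,
`and/or/not`, the functions `exp ln log10 sqrt abs pow min max`, a
single-condition `piecewise(a, cond, b)`, and the reserved time symbol
`t`. Multi-piece piecewise is deliberately outside the supported subset
(the SBML importer rejects it by name). Expressions are parsed by a small
Pratt parser into an immutable AST that round-trips through rendering;
the same AST is translated to/from SBML MathML and compiled to plain
Python for the right-hand side. Differentiation is never needed — the
solver uses finite-difference Jacobians with a conservative sparsity
pattern computed from the free symbols of each rate (rule dependencies
expanded transitively).

## Simulation

The ODE system is integrated with scipy's variable-order BDF
implementation — the Gear family of stiff multistep methods. Defaults:
`max_step = 0.1`, `rel_tol = 1e-6`, `abs_tol = 1e-9`, 501 uniform report
points. The `max_step` cap is deliberately honored even when accuracy
would permit larger steps, because event localization and dense trigger
monitoring assume the solver never strides far past a crossing.

Event handling turns each boolean trigger into a continuous signed margin
(comparisons become signed differences, `and` → `min`, `or` → `max`,
`not` → negation); the solver root-finds the margin's zero crossing,
integration stops there, all simultaneous events apply their assignments
in declaration order (values all evaluated before any assignment, so an
event sees a consistent pre-event state), and integration restarts.
Triggers true at t0 do not fire at t0; an event re-arms only after its
trigger has gone false, and because an assignment can flip its own
trigger (a refill event resetting the species it watches), arming is
recomputed from the post-assignment margin at every event boundary.

Negative concentrations are reported with a warning, never clamped:
clamping would silently integrate a different model.

## Estimation

The objective is the weighted sum of squared errors over the observation
grid; a failed or non-finite simulation scores +inf, which keeps the
optimizers out of pathological regions without special-casing. Weights
are exposed (and default to 1) because multi-scale concentrations
otherwise let the largest species dominate the fit.

* **Powell.** scipy's bounded modified Powell conjugate-direction method,
  wrapped in a restart loop: on narrow curved valleys Powell's direction
  set degenerates and the search stalls far from the optimum with a large
  gradient remaining (reproducible on a two-parameter chain fit), so the
  search restarts from the current best with a fresh axis-aligned
  direction set until a restart stops improving.
* **RCGA.** Real-coded GA with uniform initialization inside the bounds,
  BLX-α crossover (α = 0.5), per-gene Gaussian mutation (rate 0.1,
  σ = 5 % of the bound range), tournament selection of size 2 and elitism
  of one; fully reproducible from its seed. These operator choices are
  declared defaults and overridable — they are conventional, not sacred.
* **Hybrid.** The GA's best individual seeds a Powell polish; the result
  takes the better of the two phases, so `hybrid ≤ rcga` at equal seed by
  construction.

Simulation settings used during fitting are a modeling choice: the test
suite and acceptance runs fit with `max_step = 1.0` on smooth first-order
problems, which changes nothing at the observation tolerance but makes
each objective evaluation several times cheaper.

## SBML interchange

Import targets SBML Level 3 Version 1 Core (Level 2 documents that parse
under the same element names are accepted as-is). Boundary/constant
species become pools, assignment-rule targets become rule-determined
outputs, kinetic-law MathML becomes custom rate expressions with local
parameters namespaced on derivation, compartment sizes are imported as
inert named parameters (their role differs from layers; sizes stay folded
into the rate expressions exactly as written), and function definitions
are inlined. Constructs outside the supported subset raise an error that
names every offending feature — fast reactions, csymbol delay, dynamic
stoichiometry, multi-piece piecewise, rate/algebraic rules, initial
assignments, event delays/priorities — rather than being skipped.

Export flattens first (SBML has no notion of layers or shortcut symbols,
so models are stored non-layered): shortcut edges become plain
speciesReferences carrying the shortcut's stoichiometry, all parameters
are published globally under their qualified names, display names go to
`name` attributes and sanitized ids to `id`. Export correctness is
checked semantically — import(export(s)) must simulate identically to
1e-6 for every fixture — plus structural assertions on the emitted XML.

`partition` is the inverse convenience for imported (flat) models: an
explicit config assigns every element to a layer and cross-layer
participations are wired through shortcuts (listed ones first, remaining
ones auto-created carrying the edge coefficient). Partitioning never
changes the dynamics, and flattening a partition recovers the original
edge multiset. Layer connectors count species wired into a layer's
reactions, rules or events — so a "totals" layer holding only assignment
rules is still connected to the layer that owns the summed species.

## Synthetic fixtures: what they emulate, and what they do not

The fixtures module generates every model the tests use:

* the **linear chain** X1 → … → Xn (X1 a pool at 100, rate constants
  0.1) is the scaling benchmark; whether Xn has a terminal outflow is
  genuinely ambiguous in the source material, so it is a flag, defaulting
  to an outflow (which gives the clean closed form
  X2(t) = 100(1 − e^{−0.1t}) for n = 2);
* the **ATP/ADP toy** pins the per-edge coefficient semantics (1 vs 2);
  its backbone species are named S1..S4 and its rate constants are unit
  values — only the coefficient structure is asserted;
* the **butanol model** reproduces the published topology claims — two
  layers connected through acetoacetyl-CoA, NAD+ and NADH; 4 NADH
  produced on the E. coli side (2 of them at the
  glyceraldehyde-3-phosphate oxidation step) and 4 consumed on the
  C. acetobutylicum side (1 at the acetoacetyl-CoA reduction step);
  NAD+ mirrored. Its kinetics are unit-rate mass-action placeholders:
  nothing quantitative about butanol production should be read off its
  trajectories, and the tests assert only the stated structure;
* the **rule/event toy** and **random schemes** exist for closed-form and
  oracle-based checks.

Consequently the test suite demonstrates correctness of the machinery —
stoichiometry assembly, layer transparency, solver behaviour, recovery of
generating parameters from noiseless/noisy synthetic data — not fidelity
of any particular biological model: real kinetic models bring stiffness
ratios, parameter correlations and measurement-error structure these
fixtures do not emulate.

## Numerical choices and scale

* State ordering is species declaration order across layers in layer
  order, making rendering and regression output deterministic.
* The compiled right-hand side is generated Python (state unpack → pools
  and parameters from a mutable environment dict → rules in topological
  order → rate vector), multiplied through the signed stoichiometry
  matrix. On the 100-species chain at `tf = 1000` with `max_step = 0.1`
  a full run takes on the order of a second.
* Event times are grouped with a 1e-9 relative tolerance; the arming
  hysteresis uses a 1e-8 margin band.
* Test problem sizes: oracle comparisons use 3–8-species random schemes;
  estimation checks use 2–3-species chains with 6–26 observation points
  and GA budgets of a few hundred evaluations — sizes chosen so the whole
  suite exercises every path in minutes while leaving the statistics
  (medians over 10 seeds, 8/10 basin-escape wins) stable.

## Known limitations

* No compiled-code generation, MATLAB export, SBGN, or BioModels
  retrieval; no stochastic (SSA) semantics — the simulator is purely
  deterministic.
* Only single-condition piecewise; no delay differential terms.
* SBML unit definitions are ignored (values are taken as written);
  `initialAmount` is read as a concentration with a note in the import
  report.
* Michaelis–Menten modifiers influence nothing unless the law is written
  as a custom expression; the built-in law is the textbook
  Vmax·S/(Km + S) form.
* The estimators are derivative-free by design; no identifiability or
  confidence-interval analysis is provided.
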