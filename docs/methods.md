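# Methods

## Scope and model class

`hybkit` handles deterministic kinetic models: any number of
compartments (fixed positive volumes), species with non-negative initial
concentrations, constant or rule-governed parameters, irreversible or
reversible reactions with arbitrary kinetic-law expressions, rate rules
(direct ODEs on a variable) and assignment rules (instantaneous
algebraic definitions).  Events, algebraic rules, constraints, function
definitions and SBML packages (comp, fbc, layout) are out of scope; on
SBML input they are reported as warnings and dropped rather than
refused, since database models routinely carry constructs irrelevant to
the hybrid pipeline.

Three conventions are applied uniformly and are the only
transformations a round trip performs:

* **Concentrations are canonical.**  `initialAmount` on SBML input is
  divided by the compartment size once, on read.
* **One flat namespace.**  SBML kinetic-law local parameters are hoisted
  to global parameters named `<reactionId>__<localId>` and renamed
  inside the law.  HMOD has no local scopes by construction.
* **Kinetic laws are concentration rates.**  A species' derivative is
  Σ(±stoichiometry·law)/V over its reactions.  All shipped fixtures use
  V = 1.0, where SBML's substance/time reading and this one coincide;
  for V ≠ 1 the division is applied explicitly and documented here
  because SBML tools that interpret laws as substance rates will differ
  by the factor V.

## Expression layer

Kinetic mathematics lives in an immutable expression tree translated
bidirectionally between infix text (HMOD) and content MathML (SBML).
The function set is deliberately closed — `exp, ln, log10, sqrt, tanh,
abs, min, max, piecewise` plus the arithmetic operators and (for
piecewise conditions) relational operators — the smallest set covering
common kinetic laws and tanh network activations.  `tanh` has a native
content-MathML element, so compiled networks need no piecewise
emulation and load in standard simulators.

Grammar choices that matter for round-trip exactness:

* power `^` is right-associative; unary minus binds tighter than `^`
  (so `-x^2` is `(-x)^2`);
* `pow(a,b)` normalizes to `^` at parse time, and unary minus applied
  to a numeric literal folds into a negative literal, so each
  expression has one canonical tree;
* numerals serialize as the shortest decimal that round-trips the IEEE
  double bit-exactly;
* the writer inserts parentheses only where precedence or associativity
  demands; `parse(write(e)) == e` holds structurally and is
  property-tested on seeded random trees in both syntaxes, with a
  shunting-yard evaluator written independently of the tree machinery
  as the numerical oracle.

MathML reading accepts the SBML dialect (`apply`, `ci`, `cn` including
e-notation and rational forms, n-ary `plus`/`times` folded left, unary
and binary `minus`, `log` with numeric base 10, `root` of degree 2,
`piecewise`); anything else is an error naming the element.  `log10` is
written as `log` with an explicit `logbase` of 10.

## HMOD and the ANN container

`HMOD-SPEC.md` is the normative grammar.  The design drivers: pure
ASCII, one record per line, a fixed block order so definition-before-use
is checkable in one pass, and canonical serialization (stable field
order, fixed spacing, shortest numerals) so that serializing the same
model twice is byte-identical and text diffs are meaningful.  The `[ML]`
block embeds the network — per-input min/max scaling bounds, per-layer
size and activation, row-major weight records, bias vectors, and
output→target mappings — keeping a hybrid model self-contained in one
file.  The standalone `.annw` weight container reuses the same record
grammar.  Validators on both formats return ordered issue lists with
stable codes (18 HMOD-side codes, each exercised by one malformed-corpus
file); they never raise on bad input.

## Compiling a network into model constructs

Hybridization compiles a feedforward network (≥ 1 hidden layer, tanh or
linear activations) into standard constructs, all ids generated under a
collision-checked prefix (default `ann`; deterministic fallbacks
`ann_h1`, `ann_h2`, …):

* one constant parameter per weight `annW_<l>_<i>_<j>` and bias
  `annB_<l>_<i>` (origins `ml-weight` / `ml-bias`);
* one assignment rule per scaled input
  `annX_i = (x_i − min_i)/(max_i − min_i)` — bounds embedded as
  literals so they travel with the model — per hidden node
  `annH_l_i = tanh(Σ_j W·prev + b)`, and per output node `annY_k`;
* each generated rule variable is declared as a non-constant parameter
  (origin `ml-node`), which SBML requires of assignment-rule targets;
* a reaction-rate target's kinetic law is replaced by `annY_k`,
  optionally times a declared mechanistic factor (covering the common
  ρ(x)·X serial-hybrid form); a parameter target is assigned directly.

Rule evaluation in topological order therefore reproduces the forward
pass exactly (to rounding; the acceptance check demands ≤ 1e-12), and
the compiled model is valid SBML L3V2.  De-hybridization inverts the
compilation, recovering weights bit-exactly from the parameter values
and the scaling bounds from the canonical `annX` rule shape.  The one
irreversible step is the replaced kinetic law: the recovered mechanistic
model carries the declared factor (or the literal 0) in its place, so
re-hybridizing reproduces the hybrid model exactly — the direction the
pipeline needs.

## Simulation and equivalence checking

The right-hand side evaluates assignment rules in topological order
inside every integrator call (instantaneous semantics, required for
network-in-the-loop correctness), then reaction fluxes, then species
derivatives and rate rules.  Integration uses LSODA via
`scipy.integrate.solve_ivp` with defaults rtol = 1e-8, atol = 1e-10 —
stiff-capable because the fixture set includes a two-timescale toy
(rate constants 1000 vs 1), and tight enough that solver error sits far
below the 1e-8 round-trip equivalence threshold.  Trajectories carry
state columns plus derived (assignment-rule) columns, export to CSV,
and compare by per-column max-abs difference on identical grids.

For the hybrid-vs-mechanistic check the comparison bound is the
integrated rate error `fit_error × t_end`: a rate perturbation bounded
by ε can move a concentration by at most ε·t over [0, t] when the
perturbed dynamics are non-expanding, as the decaying toys here are;
both trajectories are integrated at rtol = 1e-10, atol = 1e-12 so solver
error is negligible against that bound.

## Synthetic inputs

All tests and the acceptance script run on generated inputs; nothing is
downloaded.

* **Toy models** (compartment size 1.0, seeded rate constants):
  a linear chain with U[0.1, 2] mass-action constants; a reversible
  pair conserving A+B (plus a rate-ruled clock, dc/dt = 1, to exercise
  rate rules); a Michaelis–Menten two-step pathway with V_max ∈
  U[0.5, 2], K_m ∈ U[0.2, 1], k₂ ∈ U[0.1, 1], S₀ = 2 (plus a
  `total = S + P` observable to exercise assignment rules); and the
  stiff pair above.  These cover the constructs the formats carry, not
  the scale or parameter realism of curated database models — passing
  round trips show format fidelity, not biological validity.
* **Random networks**: weights and biases U(−1, 1), tanh hidden /
  linear output, [0, 1] input scaling.
* **Rate-mimicking network**: the hybrid-vs-mechanistic input.  The
  mechanistic model is simulated once; the target reaction's law is
  sampled on the trajectory's min-max state box (5% padding; trajectory
  points plus uniform draws, 400 samples); a random-feature tanh hidden
  layer (weights U(−3, 3)) gets its linear output layer from one least
  squares solve — extreme-learning-machine style, chosen because
  iterative training is outside the tool's scope and a direct solve is
  fast and deterministic.  The achieved max-abs fit error is recorded
  in the returned metadata and defines the simulation-agreement bound.
* **Malformed corpus**: 18 HMOD and 6 SBML files, each violating
  exactly one rule; validator completeness means each file yields
  exactly its intended code and all pristine fixtures yield empty
  reports.

Problem sizes in the acceptance script — 50 round-trip models, 20
compilation pairs × 100 states, 100-point grids — keep the whole run in
the order of seconds while exercising every pipeline path; all
randomness derives from the single `--seed` argument.

## Known limitations

* SBML annotations/RDF and per-element notes are not preserved
  (model-level notes and the parameter-origin tags are); `cn` unit
  attributes are accepted but dropped.
* Reversible reactions are carried as a single signed law, not split
  into forward/backward halves.
* The simulator has no events, no steady-state solver and no time
  symbol in expressions.
* ReLU and other activations would need piecewise emulation and are a
  documented extension point, not implemented.
* The Keras-H5 reader handles dense-only architectures and assumes
  tanh hidden / linear output; the `.annw` text container is the
  supported interchange path.
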