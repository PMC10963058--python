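# Methods

## Model representation

A `Model` holds compartments, metabolites, reactions, and global
parameters. Metabolites carry an initial concentration (nM by default;
an SBML file's declared units override this, with time in seconds) and a
`fixed` flag: fixed (boundary) species are clamped and excluded from the
ODE state. Reactions carry integer stoichiometry maps for reactants and
products, modifier species with a role (inhibitor, activator, catalyst),
a reversibility flag, a rate law, and that law's local parameter values.
Metabolite and reaction id namespaces are disjoint, and every edit goes
through methods that enforce referential integrity (removing a metabolite
still referenced by a reaction is rejected; removing a reaction never
removes metabolites).

Reaction equations use the grammar
`[coef] species { + [coef] species } ("->" | "<->" | "=") ...` with `=`
accepted as a synonym for `<->` (a widespread SBML-tool dialect), omitted
coefficients defaulting to 1, and coefficients restricted to positive
integers — fractional stoichiometry is rejected with a named-token error
rather than silently rounded. Modifiers never appear in the equation
string; they are attached separately so rate expressions can reference
them.

## Rate laws

Built-in laws: irreversible mass action `k·∏[Rᵢ]^sᵢ`, reversible mass
action `kf·∏[Rᵢ]^sᵢ − kr·∏[Pⱼ]^tⱼ`, irreversible Michaelis–Menten
`V·S/(Km+S)`, reversible Michaelis–Menten
`(Vf·S/Kms − Vr·P/Kmp)/(1 + S/Kms + P/Kmp)`, and competitive-inhibition
Michaelis–Menten `V·S/(Km·(1+I/Ki)+S)` where `I` is the reaction's
inhibitor modifier. Built-in laws are structural: their concrete formula
is generated from a reaction's stoichiometry, so mass action applies at
any arity while the Michaelis–Menten forms require a single substrate
(and product, for the reversible form).

Rate-law suggestion filters a library by arity — reactant/product counts
*with stoichiometric multiplicity* (so `2A → B` is not unimolecular) —
and by matching the reversibility flag, listing mass-action variants
first and preserving library order otherwise, which makes the suggestion
deterministic.

User-defined laws use a restricted arithmetic grammar: `+ - * / ^` (or
`**`), parentheses, numeric literals, bare symbols, and the functions
`pow`, `exp`, `log`, `sqrt`. The expression is parsed into an AST and
every node is whitelisted before compilation, so model files can never
execute general code. Symbols resolve against species ids, local
parameter slots, global parameters, and compartment ids.

## Simulation

The network compiles to `dx/dt = N v(x)` over the free metabolites.
Time courses use `scipy.integrate.solve_ivp` with the LSODA
stiffness-switching method, sampled at `n_points + 1` uniform times
including t = 0 and t = duration. Default tolerances are
`rel_tol = 1e-6`, `abs_tol = 1e-12` (the common deterministic-simulator
defaults); both are exposed. Solver excursions below zero within an
`abs_tol`-scaled floor are clamped to zero; anything larger raises a
solver error rather than being hidden. Rate expressions are evaluated
with concentrations floored at zero so tiny negative excursions cannot
feed invalid powers.

Steady states are sought in two stages. First, root-finding on
`N v(x) = 0` from the initial state (scipy's Powell hybrid method, a
damped Newton-type iteration). Because Newton steps can slide off the
stoichiometric compatibility class — for a closed `A ⇌ B` system any
point with `kf·A = kr·B` is a root, but only one conserves `A + B` — a
candidate root is accepted only if every left-null-space invariant of
`N` matches the initial state to 1e-9 (relative to the state scale) and
the residual ‖N v‖∞ is below tolerance. Otherwise the solver falls back
to integrating forward over geometrically growing horizons (10 s, 100 s,
… up to 1e7 time units) until the residual criterion is met; a system
that never meets it (e.g. unbounded zero-order production with no sink)
reports `status = "not_found"` instead of raising.

Parameter scans address one value through a *parameter path* —
`global.NAME`, `reaction.RID.SLOT`, or `metabolite.MID.initial` — and run
exactly two simulations: all items at their initial values (baseline) and
all at their final values (perturbed). The scan operates on an internal
deep copy, so the input model serializes byte-identically before and
after (the restoration contract). Intermediate grid points are out of
scope; the perturbation workflow only needs the two endpoints.

## Comparative analysis

`PCᵢ = 100·(Bᵢ − Aᵢ)/Aᵢ` per metabolite, where A comes from the
reference state and B from the perturbed state, over the metabolite
intersection of the two models (matched by id first, then by exact
display name; ambiguous duplicate names raise rather than pair silently;
an empty intersection is an error). Division by zero is resolved as:
A = 0 and B = 0 gives PC = 0; A = 0 and B > 0 gives a positive infinite
sentinel, rendered "∞" and assigned the maximum node size. Time-course
comparisons use the final sampled time of a common duration by default
(any sampled time can be selected); steady-state comparisons require
both states to converge and name the failing model otherwise.

Visual mapping: node size is
`size_min + (size_max − size_min) · min(1, log10(1+|PC|)/log10(1+PC_cap))`
with `PC_cap` the largest finite |PC| in the comparison. The log
compression is deliberate — percentage changes in the drug studies span
more than six orders of magnitude, and a linear map would collapse
everything but the extremes. Positive PC colors a node red, negative
cyan; |PC| below the visibility threshold (default 1e-6 %, since "did
not vary" is never exactly zero in floating point) hides the node and
its incident edges. Tooltips carry (PC, A, B).

## File formats

SBML Level 2/3 is read and Level 3 Version 1 written through libsbml.
Boundary/constant species map to fixed metabolites; kinetic-law math is
carried as an explicit formula with local parameters kept local (a local
colliding with a global or species symbol is renamed with a reaction-id
prefix in both the slot list and the formula). Modifier roles round-trip
through SBO terms. Events, rules, and constraints raise an explicit
unsupported-feature error naming the construct. Round-trip equality is
checked structurally — ids, stoichiometry, flags, parameter values to 12
significant digits — plus numerical agreement of each reaction's rate
formula at probe states, since formula text may be reformatted in
transit.

KGML parsing preserves entries, reactions, relations, and graphics
coordinates (kept as optional layout hints, never required). Conversion
to a model applies fixed rules chosen to yield a well-formed bipartite
network: map-type entries are dropped, entries aliasing the same
compound accession merge into one metabolite (so the metabolite count
never exceeds the compound-entry count), catalyzing gene/enzyme entries
become fixed pseudo-metabolites attached as catalyst modifiers,
reactions with identical substrate/product sets merge, missing reaction
types default to irreversible, and the result is an unparameterized
topology (rate laws unset) with compound initial concentrations of 0.
Unresolvable entry references are reported as diagnostics, not silently
dropped. KGML itself carries no module membership, so modules are
supplied as a JSON side file (module id → reaction ids) — this keeps
module extraction fully offline-testable.

GraphML export types every node/edge attribute (kind, shape, color,
size, visibility, PC tooltip fields); invisible nodes are present in
GraphML with `visible=false` but omitted from rendered PNG/SVG images.
Inhibitor edges render dashed red with a T-shaped head; reversibility is
encoded in reaction-node color (blue reversible, red irreversible), not
double-headed arrows.

## Database access

KEGG REST and BRENDA queries are cache-first: every request is keyed by
the sha256 of a canonical request string and the raw response bytes are
stored under that key, so recorded responses and programmatic fixtures
are interchangeable. Offline mode never invokes a transport (tests
assert this with an injected transport that fails the test if called).
BRENDA retrieval fetches all entries for an EC number and parameter
kind; the organism filter is applied client-side, so narrowing never
re-queries. The live SOAP client is best-effort (stdlib HTTP with a
minimal envelope; credentials come from environment/config, never code)
and normalizes responses to a canonical JSON byte form before caching,
making the cache format uniform. Parameter assignment converts molar
units to the model's concentration unit (mM → nM is ×1e6; unknown units
raise), touches exactly one slot, and records provenance (EC, organism,
original value/units, pH, temperature, PubMed link) on the reaction.
Entry ranking by preferred organism and pH/temperature windows is a
helper for, never a replacement of, user selection.

## Synthetic data

`generate_synthetic_model` produces random closed networks of
single-substrate/single-product conversions: the first reactions chain
every metabolite into one weakly connected component, rate laws are
drawn from the requested mix (mass action irreversible/reversible,
irreversible Michaelis–Menten), parameters are log-uniform (first-order
constants 1e-3–1e-1 s⁻¹, V 0.1–10 nM/s, Km 1–100 nM) and initial
concentrations uniform in 0.5–10 nM. Closedness bounds all trajectories,
so generated models are guaranteed to simulate; everything is
deterministic for a fixed seed.

The signaling fixture is a synthetic 16-species receptor/kinase-cascade
model: receptor synthesis proportional to an expression constant V1
(default 100), ligand binding, recycling, and ligand-induced degradation
with rate constant k4 (default 0.2 s⁻¹); a GTPase switch with basal and
receptor-driven activation; an apex kinase whose deactivation is split
over two reactions (r17a/r17b, 2.5 s⁻¹ each) so a "disease" mutant is
created by deleting both; MEK- and ERK-like tiers; a receptor-driven Akt
arm; and a GSK3b-like regulator (phosphorylated by both ERK- and
Akt-like kinases) whose unphosphorylated form degrades a beta-catenin-like
pool. Rate constants were chosen once to place the fixture in the
dynamical regime the drug studies require: healthy apex-kinase
phosphorylation is basal (~1e-3 nM at 15 000 s, because deactivation
outruns activation 1e5-fold) while the mutant converts its whole pool on
a ~2e4-s timescale, so the mutant-vs-healthy percentage changes reach
1e6 %; drug inhibition (a Michaelis–Menten reaction scaled by drug
concentration, so a zero dose is exactly inert) reverses the cascade but
cannot reach the parallel Akt arm. One physical consequence worth
noting: with constant synthesis and first-order degradation the receptor
pools themselves scale linearly with V1, so a 40-fold expression
increase moves EGFR/pEGFR by construction while leaving every signaling
species below 1 % — "profile unchanged" statements therefore refer to
the signaling species.

What the fixture does *not* emulate: real signaling models' detailed
mass-action binding cascades, scaffolding, compartmental shuttling, or
literature-calibrated rate constants. Tests passing on the fixture
demonstrate that the machinery (mutation by deletion, drug mechanisms,
scans, percentage-change mapping) behaves correctly in the right
dynamical regime; they do not certify quantitative agreement with any
published model. Quantitative reproduction requires the deposited
accession models, fetched by the explicit `demo --download` step —
never at import or test time.

## Numerical and design choices

- Steady-state tolerance default 1e-9 on ‖N v‖∞; the acceptance of a
  Newton root additionally requires conservation-law consistency (above).
- Scan semantics are endpoint-only; scan items resolve before any
  simulation runs so a bad path fails fast.
- Percentage-change inputs are validated non-negative (concentrations);
  the sign-flip relation PC′ = −100·PC/(100+PC) under reference/perturbed
  swap is exact in real arithmetic and used as a metamorphic test.
- Layouts: force-directed (seeded, deterministic), hierarchical (layered
  by condensation topological depth, safe on cycles), and KGML-hint
  (stored pathway coordinates win; missing nodes fall back to
  force-directed placement).
- Default comparison problem sizes in tests and the acceptance script:
  15 000-s time courses at 300 output points for the signaling studies,
  25–80-s horizons at 100 points for the random-network property checks,
  and 1000-step RK4 for the independent oracle; these keep the full suite
  in the single-digit seconds while leaving integration error far below
  the asserted bounds.

## Known limitations

- SBML events, assignment/algebraic rules, and delays are unsupported by
  design; files using them are rejected explicitly.
- Stochastic simulation, flux balance analysis, sensitivity analysis,
  and parameter estimation are out of scope.
- The KGML conversion rules are a fixed, documented normalization; other
  tools may make different choices (e.g. splitting reversible reactions).
- Live BRENDA access depends on a drifting SOAP schema; the cache/fixture
  mode is the stable contract.
- Michaelis–Menten built-ins require single-substrate reactions; general
  multi-substrate enzymatic forms must be written as custom expressions.
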