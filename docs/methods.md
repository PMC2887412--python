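# Methods

## Scope and model class

The package operates on an *integrated model*: a stoichiometric metabolic
network whose reactions carry Boolean gene-protein-reaction (GPR)
expressions, together with a Boolean transcriptional-regulatory rule table
over metabolic genes, transcription factors (TFs), flux predicates and
environmental stimuli. Fluxes are steady state (`S v = 0`), in mmol/gDW/hr
(biomass in 1/hr); uptake is negative flux and an `Environment` sets
exchange lower bounds. Regulation is purely Boolean — no graded expression,
no kinetics — and overexpression means forcing an otherwise-unexpressed
gene on; it never raises a flux bound.

## Logic compilation

GPRs (AND/OR only; NOT is rejected) are expanded to disjunctive normal
form: a reaction is an OR over enzyme complexes, a complex an AND over
subunit genes. Regulatory rules may contain NOT; negation is pushed to the
literals, where a negated gene/TF/stimulus becomes a repressor effector and
a negated flux predicate flips direction (NOT "flux positive" compiles to a
negative-flux activator, the idiom rules use for uptake sensing). Absorption
pruning removes subsumed DNF terms; a configurable term cap (default 256)
turns pathological blow-ups into errors naming the offending rule. Flux
indicators use a threshold ε = 10⁻³ mmol/gDW/hr, configurable because toy
networks may operate at different flux scales. Thresholds printed inside
rule text (e.g. `nh4(e)>2`) are kept as metadata only; the compiled
indicator always uses ε.

Every declared gene appears in the compiled regulatory index: unruled
targets get a single empty condition (constitutively on), rules that reduce
to FALSE get none (never on).

## Perturbation semantics

Design MILPs use the compatibility form: `z_g ≤ y_g` (delete only expressed
genes), `w_g ≤ 1 − y_g` (overexpress only repressed metabolic genes; TFs
have no `w`), and `ŷ_g = y_g − z_g + w_g`. This is the form that makes the
intervention penalties meaningful — a deletion of an already-silent gene is
not a design. Fixed-design audits and verification instead use *forcing*
semantics (`z` wins, then `w`, then the regulatory state): an audit list may
delete a gene that happens to be off in some regulatory fixed point, and the
question asked there is "what phenotype does this genotype have", not
"is this intervention minimal".

## Regulated FBA and fixed points

`solve_regulated_fba` maximizes an objective jointly over fluxes and
Boolean variables, demanding a self-consistent assignment: flux indicators
must agree with the fluxes chosen. This is a simultaneous (steady-state)
semantics, not an iterated time-stepped one. Regulatory cycles are allowed;
when several consistent fixed points exist the solver returns whichever is
best for the objective, and the returned `BooleanState` reports which. The
solver-free evaluator (`evaluate_state`) resolves cycles by enumerating
assignments inside strongly connected components, deterministically
preferring the most-expressed fixed point, and raises a `ConsistencyError`
naming a contradictory cycle (e.g. a TF repressing itself). The flux
indicator boundary (`v` exactly at ε) is deliberately left to the solver;
practical models do not sit on it.

## Strong duality block

The inner problem is `max biomass` subject to mass balance, bounds, and
`v_j = 0` for removed reactions. The single-level reformulation emits dual
feasibility `Sᵀu − λ + μ + h̃ = p` (λ, μ ≥ 0 for lower/upper bound rows, u
free), the objective equality `p·v = Σ ub·μ − Σ lb·λ`, and conditional
duals `h̃_j` constrained to `|h̃_j| ≤ H (1 − d_j)`, so they vanish for
active reactions. Both finite bounds are dualized — the uptake-negative
convention needs upper bounds as first-class constraints — which is the
textbook generalization of a lower-bounds-only derivation. The
minimum-growth requirement (default 0.1/hr) is a lower bound *inside* the
inner LP, so a design that cannot reach it is infeasible rather than
sub-optimal.

`H` defaults to the global big-M (1000). The tighter `h_bound = 1` is
implemented and tested, but kept opt-in: it is a solve-time heuristic that
can exclude the true inner optimum on an arbitrary network, and this
package prefers exactness at the scales it targets. Every design can be
re-checked by `verify`, which re-derives growth and product by a plain
regulated re-solve (guarding against any big-M or dual-bound artifact) and
reports the coupling robustness — the *minimum* product flux over inner
optima, the pessimistic counterpart of the designer's optimistic reading.

## Designers

Big-M linearization is used throughout (global flux bound 1000 mmol/gDW/hr,
per-row spans from the actual bounds); LP/MILP work runs on HiGHS through
scipy with gap 0. Outer objective: product flux minus per-intervention
penalties α = β = 10⁻⁶, which strip interventions that do not improve
production without affecting the production term.

Enumeration uses integer cuts of Hamming distance ≥ δ (default 1) on the
intervention vector. Two deliberate refinements:

* With δ = 1, each incumbent is pruned by leave-one-out re-evaluation
  before being emitted, and both raw and pruned sets are cut. After the
  minimal optima are cut away, the MILP may return a previous optimum
  padded with a penalized-but-tied useless intervention; pruning restores
  the "minimal strategies only" reading. With δ > 1 incumbents are emitted
  unpruned so the diversity distance stays meaningful.
* The reaction designer gets the same 10⁻⁶ tie-break penalty (its reported
  objective stays the raw product flux) and superset-excluding cuts, for
  the same reason: otherwise optimal deletion sets padded with harmless
  extras are solver-tie artifacts.

Penalties stay in the objective of every successive enumeration solve,
including for δ > 1.

The bi-level reading is optimistic: the outer problem may pick the most
favourable inner optimum. `evaluate_design` reproduces exactly that
semantics for fixed designs in two stages (max growth, then max — or min —
product at that growth, window 10⁻⁹).

## Audit analyses

* `minimal_gene_cover`: minimum hitting set over the target reactions'
  enzyme complexes (exact, via MILP), with collaterally disabled reactions
  reported; targets without GPR raise an error — the genetically
  unimplementable case.
* `reevaluate_designs`: regulated (or unregulated) two-stage evaluation of
  fixed gene designs; a design is lethal when its growth optimum falls
  below the viability threshold (default 0.1/hr) or no consistent state
  exists.
* `min_overexpression_rescue`: minimizes the number of repressed genes
  forced on so that the regulated growth optimum secretes at least the
  target (default: the same design's unregulated product), using the same
  duality block with deletions fixed.
* `yield_percent`: flux-ratio yield — product flux over the LP-maximal
  product flux under the same uptake with no growth demand and no
  gene logic. A molar-yield definition would need metabolite formulas the
  model dialect does not carry; the flux-ratio definition is the package's
  choice and is stated wherever yields are printed.
* `intervention_stats`: per-gene intervention frequencies (default filter:
  15 % pooled, 10 % per method) and Pearson correlations of 0/1 indicator
  vectors; zero-variance pairs are reported as missing (NaN), never as 0.

## Synthetic data

`random_toy_model` emulates the structure the designers care about: a
substrate-to-biomass backbone with cross edges (so alternative routes
exist), two secreted by-products with different biomass yields (so coupling
is non-trivial), GPRs mixing single genes, isozyme pairs and two-subunit
complexes (plus some unassociated reactions), and TF/stimulus regulatory
rules with acyclic TF dependencies, including constitutively active
repressor TFs so that overexpression and TF deletion can matter. Biomass
yields are drawn in 0.05–0.3 per unit flux, uptake is 10 units — scales at
which the conventional 0.1/hr growth floor is a meaningful constraint.
Identical seeds give byte-identical models.

What it does **not** emulate: flux-predicate regulation (kept out so that
brute-force oracles can enumerate Boolean states exactly; the bundled
example network covers that path), reversible internal reactions, loops and
cofactor stoichiometry, and genome-scale degeneracy. A green oracle test
therefore certifies the bi-level reformulation and logic encoding on small
acyclic-regulation networks; it says nothing about solve times or numerical
behaviour at genome scale.

## Numerical choices

Feasibility/duality checks at 10⁻⁶; lethality of an unconstrained growth
solve below 10⁻⁶/hr; MILP relative gap 0; growth pinning window 10⁻⁹ for
two-stage evaluation and 10⁻⁶ for envelope sweeps (regulated envelopes at
interpolated growth levels need the slack; the resulting ≤ 10⁻⁵-scale
product overshoot relative to an exact pin is documented in the tests).
Degenerate inputs: an environment with zero uptake yields a single-row
envelope at zero growth; a zero theoretical product maximum makes yields
NaN; empty rules parse to TRUE (constitutive).

## Known limitations

Boolean regulation only; no flux-modulation interventions (up/down
regulation of expressed genes); no growth-uncoupled design objective; no
loopless/thermodynamic constraints beyond bounds; solver-tie nondeterminism
between exactly tied strategies is possible within one emitted list
position (the set of emitted strategies is stable, their internal order
among exact ties is the solver's choice). Genome-scale MILPs are supported
by the formulation but not tuned for; expect long solves with open-source
solvers and use the incumbent/gap reporting.
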