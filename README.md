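# optorf

Growth-coupled strain design over integrated metabolic and Boolean
regulatory networks.

Classical bi-level strain designers pick *reactions* to remove so that the
only way a cell can grow fast is to secrete the engineer's product — making
growth-rate selection during adaptive evolution do the optimization. Real
interventions, however, are genetic: an isozyme-backed reaction needs every
encoding gene deleted, a multi-subunit enzyme falls with any one subunit,
knockouts ripple through other reactions the same genes serve, and
transcriptional regulation can silently veto the whole plan (a repressed
gene cannot carry flux no matter what the stoichiometry allows). This
package performs the design directly over **genes and transcription factors
(TFs)** with regulation enforced, and provides the audit tools that expose
where reaction-level designs break.

## The model

Metabolism is a stoichiometric network at steady state, `S v = 0`, with flux
bounds `lb <= v <= ub` (uptake is negative flux; the environment sets
exchange lower bounds, e.g. a glucose uptake rate of 18.5 mmol/gDW/hr is a
lower bound of −18.5). Gene-protein-reaction (GPR) rules are Boolean: a
reaction `j` is feasible (`d_j = 1`) iff some enzyme complex `n ∈ N(j)` is
present (`b_n = 1`), and a complex is present iff all of its subunit genes
are expressed. Regulation is Boolean too: each gene or TF is on iff some DNF
condition over its effectors holds — effectors being TF activities, flux
indicators (`v ≥ ε` or `v ≤ −ε`, ε = 10⁻³), or environmental stimuli.

Interventions are binary: deletions `z_g` (metabolic genes and TFs, only of
expressed targets) and overexpressions `w_g` (metabolic genes only, only of
repressed ones), giving the surrogate expression
`ŷ_g = (y_g ∧ ¬z_g) ∨ (¬y_g ∧ w_g)` that drives the GPR and regulatory
layers. The design problem is

```
max   c·v − α Σ z_g − β Σ w_g                    (product, α = β = 10⁻⁶)
s.t.  v ∈ argmax { biomass | S v = 0, bounds, v_j = 0 where d_j = 0 }
      GPR, regulation, perturbation logic;  Σz ≤ K1;  Σw ≤ K2
```

solved as a single-level MILP by replacing the inner growth LP with its
strong-duality optimality conditions (dual feasibility plus
primal-objective = dual-objective, with conditional duals `h_j` active only
for removed reactions). Alternative strategies are enumerated with integer
cuts requiring at least δ intervention differences from every previous
solution. A reaction-deletion baseline (`optknock`) with the same duality
machinery, minimal gene covers, regulated re-audits, minimal overexpression
rescue, production envelopes and intervention statistics round out the
toolbox. All MILPs run on HiGHS via scipy.

## Worked example

The bundled network feeds a substrate S to biomass B through two branches:
R1 (complex G1A+G1B) → R2 (by-product P1 + 0.08 B), and R3/R4 → R5 (isozymes
G5 or G6; by-product P2 + 0.12 B). TF1 is active whenever S is taken up; it
activates G3 and G5 and represses G1A. Maximizing growth therefore uses the
P2 branch and secretes no P1.

```python
from optorf import (build_example_network, example_environment,
                    DesignSpec, enumerate_designs)

model = build_example_network()
env = example_environment(10.0)          # S uptake up to 10 units
spec = DesignSpec(product="EX_P1", k1=2, k2=1)
for s in enumerate_designs(model, env, spec, 4):
    print(sorted(s.deletions), sorted(s.overexpressions),
          round(s.growth, 4), round(s.product, 4), round(s.yield_pct, 1))
```

prints

```
['G4', 'TF1'] []      0.8 10.0 100.0
['G6', 'TF1'] []      0.8 10.0 100.0
['G5', 'G6'] ['G1A']  0.8 10.0 100.0
['G3', 'G4'] ['G1A']  0.8 10.0 100.0
```

Deleting TF1 de-represses G1A (enabling R1) *and* switches off G3 and G5, so
a single additional deletion (G4 or G6) couples P1 secretion to growth
(growth 0.8/hr, P1 at 100 % of its theoretical maximum). Without TF
deletions, three interventions are needed: remove the competing branch
(G3+G4 or G5+G6) and overexpress the repressed G1A. In contrast, the
reaction-level answer "delete R5" translates to deleting both isozymes G5
and G6 — and audits as **lethal** once regulation is applied, because G1A
stays repressed and no route to biomass remains:

```
optorf optknock --fixture example --product EX_P1 --cap 1   # -> delete R5
optorf cover    --fixture example --target R5               # -> {G5, G6}
```

The same workflow is available programmatically
(`optknock`, `minimal_gene_cover`, `reevaluate_designs`,
`min_overexpression_rescue`) and from the `optorf` command line
(`simulate`, `envelope`, `optknock`, `optorf`, `cover`, `audit`, `stats`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch — regulated wild-type FBA, design
enumeration on the example network, the reaction-deletion baseline with its
gene-cover translation, the regulated audit and overexpression rescue, and a
design solve on a seeded random model — logging each result to stderr and
writing the results JSON to `--out`.
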