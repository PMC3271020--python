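# comfba — multi-level flux balance analysis for microbial communities

Microbes rarely live alone: fermenting bacteria only thrive when a partner
removes their hydrogen, phototrophs feed whole mats with their by-products,
and competitors split a common substrate. Classical flux balance analysis
(FBA) optimizes **one** objective, which cannot express the tension between
what is best for each species and what is best for the community. `comfba`
implements a multi-level formulation for constraint-based community
modeling: a separate biomass-maximization LP for every species (the *inner*
problems), coupled by shared-metabolite mass balances into a community-level
(*outer*) optimization.

It is a library first (the importable API plus `examples/`), with a thin
`comfba` command-line front end for running configured analyses.

## The model

For each species *k* with stoichiometric matrix *S^k*, flux vector *v^k*
and biomass flux *v^k_bio*, the inner problem given its pool allocation is

```
max  v^k_bio
s.t. S^k v^k = 0                      (internal steady state)
     (S^k v^k)_i = e^k_i − u^k_i      (net production of shared metabolite i)
     lb^k ≤ v^k ≤ ub^k
```

where uptake `u^k_i ≥ 0` and export `e^k_i ≥ 0` (mmol/gDW/h) connect the
species to one pool per shared metabolite. The outer problem chooses the
inter-organism flows to maximize a community objective (total or weighted
biomass, one member's biomass, or any target flux) subject to every species
being at its own inner optimum and to the pool balances

```
Σ_k e^k_i + u^c_i  =  Σ_k u^k_i + e^c_i        for every shared i
0 ≤ u^c_i ≤ medium_i,   0 ≤ e^c_i ≤ accumulation_i
```

Two solution modes:

* **Predictive** — the optimistic bilevel problem. Inner optimality is
  encoded by KKT complementary slackness with big-M indicator binaries
  (one exact MILP, method `dual_milp`), or by the strong-duality equality
  with its bilinear dual-times-flow products solved to global optimality by
  spatial branch-and-bound (method `bilinear`). Every returned solution is
  re-certified by independent inner re-solves (per-species duality gap
  ≤ 1e-6).
* **Descriptive** — fix experimental observations (measured fluxes,
  community composition) as constraints, drop inner optimality, and report
  each member's *optimality level* `c^k = v^k_bio / v^k_bio,max` against its
  community-specific maximum: `c^k < 1` sub-optimal, `= 1` optimal, `> 1`
  super-optimal growth at another member's expense.

Interaction types (mutualism, commensalism, competition, parasitism,
amensalism) are imposed purely by restricting the admissible directions of
the inter-organism flows; community-level flux variability analysis (FVA)
reports the range of any flux, pool flow, or flow ratio while the community
objective stays at a fraction of its optimum. A brute-force grid oracle
(enumerate allocations, re-solve every inner LP) provides an
implementation-independent cross-check, and a fixtures module generates toy
communities with hand-verifiable optima.

## Worked example

An obligate syntrophic pair: fermenter A degrades 10 mmol/gDW/h of
substrate, but its fermentation is growth-coupled to hydrogen evolution, so
it can only grow if methanogen-like B consumes the hydrogen (pool
accumulation of H2 is forbidden).

```python
from comfba import certify, make_fixture, solve_predictive

community, known = make_fixture("obligate_syntrophy")
sol = solve_predictive(community)
```

prints (see `examples/02_syntrophic_pair.py`):

```
status: optimal   total biomass: 20.000 (known: 20.0)
  A: biomass 10.000, H2 net export +10.000
  B: biomass 10.000, H2 net export -10.000
pool balance residuals: {'Bx': 0.0, 'Hx': 0.0, 'Sx': 0.0}
certification gaps: {'A': 0.0, 'B': 9.99999993922529e-08}
```

Both members grow at 10 because every unit of A's growth evolves exactly
one unit of hydrogen, which B converts 1:1 into biomass; the certificates
confirm each species is optimal for its own LP given those flows. If A is
instead *measured* at half that rate, descriptive mode
(`examples/03_optimality_levels.py`) reports

```
  A: biomass 5.000, community-specific max 10.000, optimality level c = 0.500
  B: biomass 5.000, community-specific max 10.000, optimality level c = 0.500
```

— the partner is dragged to half speed too, because hydrogen transfer is
stoichiometrically tied to A's growth.

Each `examples/*.py` script is a short narrative of one capability:
single-species FBA/FVA, the predictive pair, optimality levels, interaction
types, and the oracle cross-check plus community FVA.

## Command line

```sh
comfba fixture --name obligate_syntrophy --out demo/
comfba run     --config demo/run.yaml --out demo/      # TSV+JSON solution, manifest
comfba fva     --config demo/run.yaml --target export:Hx@A
comfba oracle  --config demo/run.yaml --resolution 1.0
comfba validate --config demo/community.yaml
```

Exit codes: 0 success, 1 infeasible/unbounded, 2 configuration error.
Logs go to stderr, numbers to stdout/files.

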