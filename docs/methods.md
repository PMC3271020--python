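# Methods

## The multi-level community model

Each species *k* is a stoichiometric network with flux bounds and exactly
one biomass reaction. Its **inner problem** is the biomass-maximization LP
parameterized by the species' pool allocation: internal metabolites are
balanced to zero, while each shared metabolite *i* satisfies
`(S^k v^k)_i = e^k_i − u^k_i` with uptake `u` and export `e` as separate
nonnegative flow variables (mmol/gDW/h). Keeping the two directions as
separate variables — rather than one signed flux — is what lets interaction
types restrict directionality independently; the futile simultaneous
uptake+export this admits is suppressed in reported solutions by a
secondary minimization of total inter-organism flow (below), not by extra
binaries.

The **outer problem** chooses all flows to maximize a community objective
subject to one mass balance per shared pool,
`Σ_k e^k_i + u^c_i = Σ_k u^k_i + e^c_i`, with environmental supply
`u^c_i ∈ [0, medium_i]` and accumulation `e^c_i ∈ [0, accumulation_i]`
(an accumulation bound of 0 forbids a metabolite from piling up — the
standard setting for syntrophic intermediates such as hydrogen or formate;
terminal by-products get +inf). Biomass flux is taken as proportional to
biomass abundance, so composition data enter as flux-ratio constraints.

Constraints attach at a level: *inner* constraints (fixed fluxes, flux
ratios, bound overrides inside one species) reshape that species' own
optimization problem — its inner optimum already accounts for them —
whereas *outer* constraints (biomass ratios, pool-flow values) restrict
only the community configuration.

## Predictive mode

Predictive mode is an optimistic bilevel program: maximize the outer
objective over flow configurations such that every species' flux vector is
optimal for its inner LP given its flows; among alternate inner optima the
outer-favourable one is selected. Two single-level reformulations are
implemented:

**`dual_milp` (default).** KKT conditions of each inner LP: primal
feasibility (already in the joint program), dual feasibility
`(A^k)ᵀ λ^k + μ^k_ub − μ^k_lb = c^k`, and complementary slackness encoded
with indicator binaries and big-M constants — `μ ≤ M_d·y` and
`(bound slack) ≤ min(ub−lb, M_p)·(1−y)`. Because the flows enter only the
primal right-hand sides, the encoding is exactly linear and the whole
problem is one MILP (solved with HiGHS through `scipy.optimize.milp`,
`mip_rel_gap = 0`). Binaries are only created where a bound is finite and
non-degenerate; variables pinned by fixed-flux constraints need none.

**`bilinear`.** The strong-duality equality
`c^kᵀ v^k = Σ_i λ^k_i (e^k_i − u^k_i) + μ_ubᵀ ub − μ_lbᵀ lb` keeps the
dual-times-flow products explicitly; the resulting nonconvex bilinear
program is solved to global optimality by spatial branch-and-bound.
McCormick envelopes relax each product `λ·n` over the (finite) net-flow box
and the dual box `[−M, M]`; branching subdivides only the *net-flow* boxes,
because the envelopes become exact as a flow box collapses while the duals
are linear once the flows are fixed. Incumbents are generated at every node
by fixing the candidate allocation and re-solving all inner LPs, so each
incumbent is feasible and certified by construction. Termination at
relative gap 1e-6, node cap 4000.

**Big-M protocol.** Default `M = 1e3` for duals and primal slacks. After
every solve the solution is validated: no primal slack jammed at an
artificial cap, and — more importantly — each inner LP is independently
re-solved at the returned allocation; the re-solve's own dual multipliers
must fit strictly inside the big-M box and the duality gap must be ≤ 1e-6.
(The MILP's internal dual variables are *not* checked against the cap: on a
degenerate optimal face the solver may park them anywhere in the box
without invalidating the certificate.) A failed certificate doubles M, up
to three times, then errors. The re-solve pins the allocation within a
±1e-8 band rather than exactly, since the MILP works to ~1e-9 feasibility
and the LP re-solve to 1e-10 — exact pinning would spuriously reject
solver round-off.

**Determinism.** After the optimum is found, a secondary solve minimizes
total inter-organism flow `Σ(u + e + u^c + e^c)` at the (epsilon-pinned)
optimal outer value, then the reported vertex is polished. This removes
futile flow cycles and makes reported solutions unique in practice; the
solver is deterministic given this tie-break.

**Diagnostics.** An infeasible community is re-examined without the
inner-optimality coupling; if the single-level relaxation is itself
infeasible, an elastic version (slack on every pool balance and constraint
row, minimize total violation) names the implicated balances/constraints.

## Descriptive mode and optimality levels

Three stages. (1) Community-specific maxima `v^k_bio,max`: the predictive
solve under environmental/structural constraints only — each species'
maximum in the context of all members striving to grow maximally.
(2) A single-level LP: all steady-state, bound, pool and interaction
constraints plus the experimental constraints, inner optimality *not*
enforced, outer objective maximized. (3) Optimality levels
`c^k = v^k_bio / v^k_bio,max`; when `v^k_bio,max = 0` the level is reported
as NaN — a species growing despite a zero community-specific maximum is
super-optimal by depletion of other members' resources, and no finite ratio
expresses that.

Stage 2 deliberately relaxes the inner problems to feasibility rather than
scaling their objectives: sub-optimality levels are identical either way,
and relaxation keeps mixed sub/super-optimal configurations
well-defined in a single LP. This was a genuinely open design point; the
relax-to-feasibility variant was chosen for its transparency and because
super-optimality is only meaningful against the stage-1 maxima anyway.

## Interaction typology

All interaction kinds reduce to directionality rules per shared metabolite:
species outside the producer set may not export it, species outside the
consumer set may not take it up; `must_consume_all` zeroes the pool's
accumulation bound. Competition is the special case of an empty producer
set over a common medium bound; mutualism is two (or more) metabolites with
opposite roles; commensalism/parasitism differ only in which back-flows are
pinned to zero. The inhibitory ("negative effect") arm of amensalism or
parasitism is modeled as a mandatory drain flux in the affected species,
linearly coupled to the producer's export with a user-supplied coefficient
— a deliberately kinetic-free encoding, since no rate law is assumed
anywhere in the framework. Rules are stored declaratively and re-derived on
use, so applying an interaction is idempotent.

## Community flux variability analysis

Minimize/maximize a target (reaction flux, pool flow, or ratio of two
flows) subject to the outer objective ≥ fraction × its optimum, with the
full inner-optimality encoding retained. Uptake/export targets are
measured as *net* flows in the named direction — the raw separated
variables admit futile two-way flow that would make their individual
ranges meaningless. Ratio targets are resolved by bisection on the
feasibility of `num − r·den = 0` (60 iterations, tolerance 1e-6), which
requires the denominator to stay positive over the examined region.

## The grid oracle

An implementation-independent verifier, not a production solver: enumerate
allocations of the inter-organism flows on a regular grid, solve every
species' inner LP at each allocation (optimistically resolving alternate
optima against the outer objective), discard allocations violating pool or
direction bounds, keep the best outer value. Design choices that keep it
honest *and* tractable:

* Enumeration runs over **net** flows, one dimension per (species,
  metabolite) pair for metabolites shared by ≥ 2 species, with the last
  toucher eliminated through the pool balance (balances then hold exactly),
  plus one environment dimension where a pool has supply or may accumulate.
* Metabolites touched by a single species couple nothing and are relaxed to
  interval row-bounds inside that species' LP — equivalent for the optimum,
  exponentially cheaper.
* Grids are anchored at zero (integer multiples of the resolution clipped
  to the feasible range from the single-level relaxation), so the
  do-nothing allocation is always examined when admissible; ranges must be
  finite or the oracle refuses.

The oracle is a lower bound at finite resolution; on the integer-coefficient
fixtures at resolution 1 it attains the exact optimum, and the test suite
checks `|solver − oracle| ≤ resolution + 1e-6` across 50+ communities.

Certification (`certify`) re-solves each inner LP at a returned solution's
allocation and reports `z^k − v^k_bio` per species; predictive solutions
must certify to ≤ 1e-6.

## Synthetic communities

The fixtures module generates the desk-scale study systems. Coefficients
are small integers so optima are hand-verifiable; every generated model
passes validation and admits the zero flux vector. Defaults: substrate
supply 10 mmol/gDW/h (transport capacities of the same order, consumers
slightly over-provisioned at 2× so supply, not transport, limits); the
syntrophic pair couples hydrogen evolution 1:1 to the fermenter's growth,
which is the mechanism that makes the association obligate; intermediate
pools default to zero accumulation. The random topology draws 2–3 species
around one growth-coupled cross-fed metabolite with integer yields 1–3,
by-product yields 1–2, and integer transport caps 3–9 — chosen so optimal
allocations sit on the unit grid and the oracle comparison is exact.

What these fixtures emulate is the *coupling structure* of real consortia
(obligate transfer, competition for a bounded niche, commensal chains);
what they do not emulate is genome-scale network statistics, realistic
yields, maintenance energy, or thermodynamic feasibility. Passing tests
therefore demonstrate correctness of the optimization machinery and the
interaction encodings, not predictive accuracy for any real organism —
applying the framework to real communities requires curated genome-scale
models supplied as SBML.

## Numerical choices

* LP feasibility 1e-10 / optimality 1e-7 (HiGHS); MILP `mip_rel_gap` 0.
* Certification tolerance 1e-6 on inner duality gaps; pool-balance
  residual tolerance 1e-9 in tests.
* Outer-optimum pinning for tie-breaks/FVA uses a 1e-9 epsilon.
* Degenerate inputs: fixed variables (lb = ub) get no complementarity
  binaries; infinite bounds get no dual variable on that side; a medium of
  `-1` or rules referencing unknown ids are configuration errors, while
  lb > ub on a reaction is a report-level validation issue (the solve then
  surfaces infeasibility).
* Flux unit is fixed at mmol/gDW/h throughout; unit conversion of source
  data is the caller's responsibility.

## Known limitations

Inner objectives other than biomass (e.g. minimization-of-adjustment
variants), parsimonious FBA, thermodynamic constraints, dynamic
(time-stepped) extensions with biomass carry-over, and strain-design outer
objectives are out of scope. SBML is read-only. The oracle scales only to
~3 species / 2 coupled metabolites by design. Ratio FVA assumes the
feasible ratio set is an interval, which holds for the convex per-binary
regions examined here but is not guaranteed for pathological mixed-integer
geometries.
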