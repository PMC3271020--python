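"""Descriptive mode: how optimally does each member grow?

Suppose the fermenter was measured to grow at 5 mmol/gDW/h — half of what
predictive mode says it could. Descriptive mode fixes that observation,
re-optimizes the community, and reports each member's optimality level
c_k = (realized biomass) / (community-specific maximum): both members come
out at 0.5, because hydrogen evolution is growth-coupled and the partner
can only eat what the fermenter evolves. c < 1 is sub-optimal, c = 1
optimal, c > 1 super-optimal (growth at another member's expense).
"""

from comfba import ConstraintSpec, make_fixture, solve_descriptive

community, _ = make_fixture("obligate_syntrophy")
measured = [ConstraintSpec.fixed_flux("biomass:A", 5.0)]
sol = solve_descriptive(community, experimental=measured)

print(f"status: {sol.status}   total biomass: {sol.objective:.3f}")
for k in community.species_ids:
    print(f"  {k}: biomass {sol.biomass(k):.3f}, "
          f"community-specific max {sol.v_max[k]:.3f}, "
          f"optimality level c = {sol.c[k]:.3f}")
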