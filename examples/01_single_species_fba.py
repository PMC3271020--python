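"""Flux balance analysis of one species in isolation.

Builds the syntrophic fermenter from the toy pair, maximizes its biomass
with shared metabolites treated as an open boundary, and scans flux
variability. The optimum (10 mmol/gDW/h) equals the substrate transport
capacity because growth is stoichiometrically 1:1 with substrate here; the
hydrogen transporter is forced to 10 at the optimum (H2 evolution is
growth-coupled) but free below it.
"""

from comfba import make_fixture, solve_fba, solve_fva

community, _ = make_fixture("obligate_syntrophy")
fermenter = community.species_by_id("A")

sol = solve_fba(fermenter)
print(f"biomass optimum: {sol.objective:.3f} mmol/gDW/h")
for rid, v in sol.values.items():
    print(f"  {rid:5s} {v:8.3f}")

for fraction in (1.0, 0.0):
    lo, hi = solve_fva(fermenter, ["tH"], fraction)["tH"]
    print(f"H2 export range at {fraction:.0%} of optimum: [{lo:.3f}, {hi:.3f}]")
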