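"""Cross-checking the exact solver, and community flux variability.

The grid oracle enumerates inter-organism flow allocations by brute force
and re-solves every inner LP at each grid point — an implementation-
independent lower bound that must coincide with the exact multilevel solve
on these small communities. Community FVA then asks which transfers are
*forced*: at the community optimum the hydrogen transfer is pinned at 10,
while without an objective floor the partner's biomass can range over
[0, 10].
"""

from comfba import FixtureSpec, community_fva, grid_oracle, make_fixture, solve_predictive

community, _ = make_fixture(FixtureSpec("random", seed=11))
sol = solve_predictive(community)
res = grid_oracle(community, resolution=1.0)
print(f"random community: solver {sol.objective:.3f}, "
      f"oracle {res.best_objective:.3f} ({res.evaluations} grid points)")

f1, _ = make_fixture("obligate_syntrophy")
for target, fraction in (("export:Hx@A", 1.0), ("biomass:B", 0.0)):
    lo, hi = community_fva(f1, target=target, fraction=fraction)
    print(f"FVA {target} at fraction {fraction:.0%}: [{lo:.3f}, {hi:.3f}]")
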