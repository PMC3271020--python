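"""Interaction typing: competition vs. a commensal chain.

Interaction types are encoded purely as directionality restrictions on the
inter-organism flows. Under competition for one substrate the community
optimum hands everything to the better converter (yield 1 beats yield 0.5).
In the commensal chain each member's by-product feeds the next, so all
three grow at the substrate-limited rate.
"""

from comfba import make_fixture, solve_predictive

competition, _ = make_fixture("competition")
sol = solve_predictive(competition)
print("competition for 10 mmol/gDW/h of substrate:")
for k in competition.species_ids:
    print(f"  species {k}: uptake {sol.uptake[k]['Sx']:.2f}, "
          f"biomass {sol.biomass(k):.2f}")

chain, _ = make_fixture("commensal_chain")
sol = solve_predictive(chain)
print(f"commensal chain (A -> B -> C), total biomass {sol.objective:.2f}:")
for k in chain.species_ids:
    print(f"  {k}: biomass {sol.biomass(k):.2f}")
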