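"""Community assembly, interaction typing, and constraint attachment."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comfba import (
    ConfigurationError,
    ConstraintSpec,
    InteractionRule,
    InteractionSpec,
    add_constraint,
    apply_interaction,
    build_community,
    make_fixture,
    parse_flow_ref,
    solve_descriptive,
    solve_predictive,
)
from comfba._program import CommunityProgram


class TestBuildCommunity:
    def test_one_pool_balance_per_shared_metabolite(self, f1):
        com, _ = f1
        program = CommunityProgram(com)
        assert set(program.pool_rows) == {"Sx", "Hx", "Bx"}

    def test_flow_variables_auto_created(self, f1):
        com, _ = f1
        pairs = set(com.flow_pairs())
        assert ("A", "Sx") in pairs and ("A", "Hx") in pairs and ("B", "Hx") in pairs
        assert ("B", "Sx") not in pairs  # B never touches the substrate

    def test_negative_medium_bound_rejected(self, f1):
        com, _ = f1
        with pytest.raises(ConfigurationError, match=">= 0"):
            build_community(com.species, medium={"Sx": -1.0})

    def test_shared_id_declared_nowhere_rejected(self, f1):
        com, _ = f1
        with pytest.raises(ConfigurationError, match="no species"):
            build_community(com.species, shared_ids=["Sx", "Zz"])

    def test_single_species_with_empty_medium_cannot_grow(self, species_a):
        com = build_community([species_a], medium={},
                              accumulation={"Hx": math.inf, "Bx": math.inf})
        sol = solve_predictive(com)
        assert sol.optimal and sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_shared_internal_conflict_rejected(self, species_a, species_b):
        from comfba.model import Metabolite, Reaction, SpeciesModel

        clash = SpeciesModel(
            "C", [Metabolite("Hx", shared=False), Metabolite("z")],
            [Reaction("r", {"Hx": -1, "z": 1}, 0, 1),
             Reaction("bio", {"z": -1}, 0, 1, is_biomass=True)],
        )
        with pytest.raises(ConfigurationError, match="shared in one species"):
            build_community([species_a, clash])


class TestInteractions:
    def test_competition_shares_the_medium_bound(self, f2):
        com, _ = f2
        sol = solve_predictive(com)
        total_uptake = sol.uptake["1"]["Sx"] + sol.uptake["2"]["Sx"]
        assert total_uptake <= 10.0 + 1e-9
        # no inter-species production of the contested substrate
        assert sol.export["1"]["Sx"] == pytest.approx(0.0, abs=1e-9)
        assert sol.export["2"]["Sx"] == pytest.approx(0.0, abs=1e-9)

    def test_mutualism_must_consume_all_couples_flows(self, f1):
        com, _ = f1
        sol = solve_predictive(com)
        assert sol.export["A"]["Hx"] == pytest.approx(sol.uptake["B"]["Hx"], abs=1e-9)

    def test_neutral_spec_changes_nothing(self, f2):
        com, _ = f2
        before = solve_predictive(com).objective
        neutral = apply_interaction(com, InteractionSpec("neutral"))
        # neutral has no rules: directionality restrictions disappear
        assert solve_predictive(neutral).objective == pytest.approx(before)

    def test_apply_interaction_is_idempotent(self, f1):
        com, _ = f1
        again = apply_interaction(com, com.interaction)
        assert again.effective_flow_bounds() == com.effective_flow_bounds()
        assert again.effective_accumulation() == com.effective_accumulation()

    def test_rule_with_unknown_metabolite_rejected(self, f1):
        com, _ = f1
        bad = InteractionSpec("custom", (InteractionRule("Zz"),))
        with pytest.raises(ConfigurationError, match="unknown shared metabolite"):
            apply_interaction(com, bad)

    def test_amensalism_cost_coupling_forces_the_drain(self, f1):
        # B must absorb an inhibitory-cost flux proportional to A's by-product
        # export; model the cost as a mandatory drain through B's hydrogen pool
        from comfba.model import Metabolite, Reaction, SpeciesModel

        com, _ = f1
        b = com.species_by_id("B")
        b2 = SpeciesModel(
            "B",
            b.metabolites,
            b.reactions + [Reaction("drain", {"Hb": -1}, 0, math.inf)],
        )
        com2 = build_community([com.species_by_id("A"), b2],
                               medium=com.medium, accumulation=com.accumulation)
        rules = com.interaction.rules + (InteractionRule(
            "Bx", producers=frozenset({"A"}), consumers=frozenset(),
            cost_coupling=("B", "drain", 0.1, "A"),
        ),)
        com2 = apply_interaction(com2, InteractionSpec("amensalism", rules))
        sol = solve_predictive(com2)
        assert sol.optimal
        assert sol.fluxes["B"]["drain"] == pytest.approx(
            0.1 * sol.export["A"]["Bx"], abs=1e-6
        )
        # the drain diverts hydrogen from methanogenesis
        assert sol.biomass("B") < 10.0 - 1e-6


class TestConstraints:
    def test_unknown_reference_rejected(self, f1):
        com, _ = f1
        with pytest.raises(ConfigurationError):
            add_constraint(com, ConstraintSpec.fixed_flux("A:nope", 1.0, level="inner"))

    def test_inner_constraint_must_stay_within_one_species(self, f1):
        com, _ = f1
        spec = ConstraintSpec.flux_ratio("A:rA", "B:rB", 1.0, level="inner")
        with pytest.raises(ConfigurationError, match="one species"):
            add_constraint(com, spec)

    def test_outer_constraint_rejects_non_biomass_reactions(self, f1):
        com, _ = f1
        spec = ConstraintSpec.fixed_flux("A:rA", 1.0, level="outer")
        with pytest.raises(ConfigurationError, match="biomass fluxes or pool flows"):
            add_constraint(com, spec)

    def test_fixing_substrate_transport_to_zero_kills_community(self, f1):
        com, _ = f1
        com = add_constraint(com, ConstraintSpec.fixed_flux("A:tS", 0.0, level="inner"))
        sol = solve_predictive(com)
        assert sol.optimal and sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_unit_biomass_ratio_recovers_symmetric_optimum(self, f1):
        com, _ = f1
        sol = solve_descriptive(
            com, experimental=[ConstraintSpec.biomass_ratio("A", "B", 1.0)]
        )
        assert sol.biomass("A") == pytest.approx(sol.biomass("B"), abs=1e-6)
        assert sol.biomass("A") == pytest.approx(10.0, abs=1e-6)

    def test_inner_flux_ratio_lives_in_that_species_problem_only(self, f1):
        com, _ = f1
        com = add_constraint(
            com, ConstraintSpec.flux_ratio("A:tB", "A:rA", 0.05, level="inner")
        )
        program = CommunityProgram(com)
        ratio_rows = [r for r, lbl in program.constraint_rows.items() if "flux_ratio" in lbl]
        assert len(ratio_rows) == 1
        assert ratio_rows[0] in program.species_rows["A"]
        assert ratio_rows[0] not in program.species_rows["B"]

    def test_inner_ratio_reshapes_that_species_optimum(self, f1):
        # forcing A to shunt by-product through tB at 5% of fermentation flux
        # keeps the model feasible and certified
        com, _ = f1
        com = add_constraint(
            com, ConstraintSpec.flux_ratio("A:tB", "A:rA", 0.05, level="inner")
        )
        sol = solve_predictive(com)
        assert sol.optimal
        assert sol.fluxes["A"]["tB"] == pytest.approx(
            0.05 * sol.fluxes["A"]["rA"], abs=1e-6)
        assert max(sol.inner_gaps.values()) <= 1e-6

    @settings(deadline=None, max_examples=10)
    @given(perm=st.permutations(range(3)))
    def test_constraints_commute(self, perm):
        com, _ = make_fixture("obligate_syntrophy")
        specs = [
            ConstraintSpec.fixed_flux("biomass:A", 5.0),
            ConstraintSpec.flux_ratio("A:tB", "A:rA", 2.0, level="inner"),
            ConstraintSpec.bound_override("A:tS", 0.0, 8.0, level="inner"),
        ]
        for idx in perm:
            com = add_constraint(com, specs[idx])
        sol = solve_descriptive(com)
        assert sol.objective == pytest.approx(10.0, abs=1e-6)


class TestPoolConservation:
    @pytest.mark.parametrize("name", ["obligate_syntrophy", "competition",
                                      "commensal_chain"])
    def test_shared_pools_balance_in_returned_solutions(self, name):
        com, _ = make_fixture(name)
        sol = solve_predictive(com)
        assert max(abs(v) for v in sol.pool_residuals().values()) <= 1e-9


class TestFlowRefs:
    @pytest.mark.parametrize("text,kind", [
        ("A:rA", "reaction"), ("biomass:A", "biomass"), ("uptake:Hx@B", "uptake"),
        ("export:Hx@A", "export"), ("medium:Sx", "medium"), ("accumulation:Bx", "accumulation"),
    ])
    def test_parse_round_trip(self, text, kind):
        ref = parse_flow_ref(text)
        assert ref.kind == kind
        assert str(ref) == text

    def test_garbage_rejected(self):
        with pytest.raises(ConfigurationError):
            parse_flow_ref("nocolon")
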