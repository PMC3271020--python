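"""Predictive/descriptive solving, community FVA, scenario batches."""

import math

import pytest

from comfba import (
    ConstraintSpec,
    FixtureSpec,
    OuterObjective,
    Scenario,
    SolverOptions,
    build_community,
    community_fva,
    compute_species_maxima,
    make_fixture,
    run_scenarios,
    solve_descriptive,
    solve_fba,
    solve_predictive,
)


class TestPredictive:
    @pytest.mark.parametrize("method", ["dual_milp", "bilinear"])
    def test_syntrophic_pair_grows_symmetrically(self, f1, method):
        com, known = f1
        sol = solve_predictive(com, method=method)
        assert sol.optimal
        assert sol.objective == pytest.approx(known, abs=1e-6)
        assert sol.biomass("A") == pytest.approx(10.0, abs=1e-6)
        assert sol.biomass("B") == pytest.approx(10.0, abs=1e-6)
        assert max(sol.inner_gaps.values()) <= 1e-6

    @pytest.mark.parametrize("method", ["dual_milp", "bilinear"])
    def test_competition_goes_to_the_better_converter(self, f2, method):
        com, known = f2
        sol = solve_predictive(com, method=method)
        assert sol.objective == pytest.approx(known, abs=1e-6)
        assert sol.uptake["1"]["Sx"] == pytest.approx(10.0, abs=1e-6)
        assert sol.uptake["2"]["Sx"] == pytest.approx(0.0, abs=1e-6)

    def test_single_species_community_reduces_to_fba(self, species_a):
        com = build_community([species_a], medium={"Sx": math.inf},
                              accumulation={"Hx": math.inf, "Bx": math.inf})
        sol = solve_predictive(com)
        assert sol.objective == solve_fba(species_a).objective

    def test_partner_objective_keeps_everyone_inner_optimal(self, f1):
        # maximizing only the methanogen still requires the syntroph to sit
        # at its own optimum given its allocation (optimistic bilevel)
        com, _ = f1
        sol = solve_predictive(com, OuterObjective.single("B"))
        assert sol.biomass("B") == pytest.approx(10.0, abs=1e-6)
        assert max(sol.inner_gaps.values()) <= 1e-6

    def test_infeasible_outer_constraints_are_diagnosed(self, f1):
        from comfba import add_constraint

        com, _ = f1
        com = add_constraint(com, ConstraintSpec.fixed_flux("biomass:A", 5.0))
        com = add_constraint(com, ConstraintSpec.fixed_flux("biomass:A", 7.0))
        sol = solve_predictive(com)
        assert sol.status == "infeasible"
        assert sol.meta["violated"]  # names the irreconcilable constraints

    def test_weighted_objective_reweights_the_optimum(self, f2):
        com, _ = f2
        # weight species 2 enough and the substrate goes to it instead
        sol = solve_predictive(com, OuterObjective.weighted({"1": 1.0, "2": 3.0}))
        assert sol.uptake["2"]["Sx"] == pytest.approx(10.0, abs=1e-6)
        assert sol.objective == pytest.approx(15.0, abs=1e-6)


class TestSpeciesMaxima:
    def test_syntrophy_maxima_are_symmetric(self, f1):
        com, _ = f1
        assert compute_species_maxima(com) == pytest.approx({"A": 10.0, "B": 10.0})

    def test_loser_of_competition_has_zero_maximum(self, f2):
        com, _ = f2
        assert compute_species_maxima(com) == pytest.approx({"1": 10.0, "2": 0.0})

    def test_empty_medium_gives_all_zeros(self, f1):
        com, _ = f1
        from dataclasses import replace

        starved = replace(com, medium={}, constraints=list(com.constraints))
        vmax = compute_species_maxima(starved)
        assert vmax == pytest.approx({"A": 0.0, "B": 0.0}, abs=1e-9)

    def test_alternate_optimum_ranges_are_tight_here(self, f1):
        com, _ = f1
        vmax, ranges = compute_species_maxima(com, with_ranges=True)
        for k, (lo, hi) in ranges.items():
            assert lo == pytest.approx(vmax[k], abs=1e-6)
            assert hi == pytest.approx(vmax[k], abs=1e-6)


class TestDescriptive:
    def test_half_speed_syntroph_drags_partner_to_half(self, f1):
        # fixing the syntroph at half its maximum limits hydrogen transfer
        # to half, so both optimality levels are 0.5
        com, _ = f1
        sol = solve_descriptive(
            com, experimental=[ConstraintSpec.fixed_flux("biomass:A", 5.0)]
        )
        assert sol.c["A"] == pytest.approx(0.5, abs=1e-6)
        assert sol.c["B"] == pytest.approx(0.5, abs=1e-6)
        assert sol.v_max == pytest.approx({"A": 10.0, "B": 10.0})

    def test_predictive_composition_is_self_consistent(self, f1):
        com, _ = f1
        p = solve_predictive(com)
        sol = solve_descriptive(com, experimental=[
            ConstraintSpec.fixed_flux("biomass:A", p.biomass("A")),
            ConstraintSpec.fixed_flux("biomass:B", p.biomass("B")),
        ])
        for ck in sol.c.values():
            assert ck == pytest.approx(1.0, abs=1e-6)

    def test_super_optimality_marker_when_maximum_is_zero(self, f2):
        # forcing equal biomass lets the worse converter grow even though its
        # community-specific maximum is zero: marked, not a number
        com, _ = f2
        sol = solve_descriptive(
            com, experimental=[ConstraintSpec.biomass_ratio("2", "1", 1.0)]
        )
        assert sol.c["1"] < 1.0
        assert math.isnan(sol.c["2"])
        assert sol.biomass("2") > 1.0  # grew at the other member's expense

    def test_infeasible_experiment_reports_violated_subset(self, f1):
        com, _ = f1
        sol = solve_descriptive(com, experimental=[
            ConstraintSpec.fixed_flux("biomass:B", 25.0),  # beyond any supply
        ])
        assert sol.status == "infeasible"
        assert any("biomass:B" in v for v in sol.meta["violated"])


class TestCommunityFVA:
    def test_hydrogen_transfer_is_forced_at_the_optimum(self, f1):
        com, _ = f1
        assert community_fva(com, target="export:Hx@A", fraction=1.0) == \
            pytest.approx((10.0, 10.0), abs=1e-6)

    def test_by_product_accumulation_is_stoichiometrically_pinned(self, f1):
        com, _ = f1
        assert community_fva(com, target="export:Bx@A", fraction=1.0) == \
            pytest.approx((20.0, 20.0), abs=1e-6)

    def test_partner_biomass_ranges_freely_without_objective_floor(self, f1):
        com, _ = f1
        assert community_fva(com, target="biomass:B", fraction=0.0) == \
            pytest.approx((0.0, 10.0), abs=1e-6)

    def test_ratio_target_is_locked_here(self, f1):
        com, _ = f1
        lo, hi = community_fva(
            com, target=("export:Hx@A", "biomass:A"), fraction=1.0
        )
        assert lo == pytest.approx(1.0, abs=1e-5)
        assert hi == pytest.approx(1.0, abs=1e-5)


class TestScenarios:
    def test_substrate_availability_scales_the_community(self, f1):
        com, _ = f1
        sols = run_scenarios(com, [
            Scenario(name=f"Sx={b}", medium={"Sx": float(b)}) for b in (2, 5, 10)
        ])
        assert [s.objective for s in sols] == pytest.approx([4.0, 10.0, 20.0])

    def test_total_biomass_monotone_in_limiting_substrate(self, f1):
        com, _ = f1
        values = [
            solve_predictive(
                __import__("dataclasses").replace(
                    com, medium={"Sx": float(b)}, constraints=list(com.constraints))
            ).objective
            for b in (0, 1, 3, 7, 10)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))

    def test_empty_batch(self, f1):
        com, _ = f1
        assert run_scenarios(com, []) == []

    def test_failures_are_recorded_without_aborting(self, f1):
        com, _ = f1
        contradictory = (
            ConstraintSpec.fixed_flux("biomass:A", 5.0),
            ConstraintSpec.fixed_flux("biomass:A", 7.0),
        )
        sols = run_scenarios(com, [
            Scenario(name="ok1"),
            Scenario(name="bad", constraints=contradictory),
            Scenario(name="ok2"),
        ])
        assert [s.status for s in sols] == ["optimal", "infeasible", "optimal"]
        assert [s.meta["scenario"] for s in sols] == ["ok1", "bad", "ok2"]


class TestMethodAgreement:
    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_bilinear_matches_dual_milp_on_random_communities(self, seed):
        com, _ = make_fixture(FixtureSpec("random", seed=seed))
        a = solve_predictive(com, method="dual_milp")
        b = solve_predictive(com, method="bilinear",
                             options=SolverOptions(big_m=100.0))
        assert a.optimal and b.optimal
        assert b.objective == pytest.approx(a.objective, abs=1e-5)
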