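"""Grid-oracle verification and independent optimality certification."""

import copy

import pytest

from comfba import (
    FixtureSpec,
    certify,
    grid_oracle,
    make_fixture,
    solve_predictive,
)


class TestGridOracle:
    def test_syntrophy_optimum_found_exhaustively(self, f1):
        com, known = f1
        res = grid_oracle(com, resolution=1.0)
        assert res.best_objective == pytest.approx(known, abs=1e-6)
        assert res.best_biomass == pytest.approx({"A": 10.0, "B": 10.0}, abs=1e-6)
        # one coupling metabolite (hydrogen), range 0..10 at step 1
        assert res.evaluations == 11

    def test_competition_optimum_found_exhaustively(self, f2):
        com, known = f2
        res = grid_oracle(com, resolution=1.0)
        assert res.best_objective == pytest.approx(known, abs=1e-6)

    def test_coarse_grid_sees_only_the_zero_allocation(self, f1):
        com, _ = f1
        res = grid_oracle(com, resolution=100.0)
        assert res.evaluations == 1
        assert res.best_objective == pytest.approx(0.0, abs=1e-9)

    def test_refining_resolution_never_worsens_the_bound(self, chain):
        com, _ = chain
        coarse = grid_oracle(com, resolution=2.0)
        fine = grid_oracle(com, resolution=1.0)
        assert fine.best_objective >= coarse.best_objective - 1e-12

    def test_oracle_is_a_lower_bound_on_the_exact_solver(self):
        for seed in range(8):
            com, _ = make_fixture(FixtureSpec("random", seed=seed))
            sol = solve_predictive(com)
            res = grid_oracle(com, resolution=1.0)
            assert res.best_objective <= sol.objective + 1e-6

    def test_best_allocation_balances_the_pools(self, f1):
        com, _ = f1
        res = grid_oracle(com, resolution=1.0)
        for i in com.shared_ids:
            produced = sum(res.best_allocation[(k, i)][1] for k in com.touchers(i))
            consumed = sum(res.best_allocation[(k, i)][0] for k in com.touchers(i))
            env = com.medium.get(i, 0.0)
            assert consumed <= produced + env + 1e-6


class TestCertify:
    def test_predictive_solutions_certify_to_zero(self, f1):
        com, _ = f1
        gaps = certify(solve_predictive(com), com)
        assert gaps == pytest.approx({"A": 0.0, "B": 0.0}, abs=1e-6)

    def test_descriptive_solution_is_allocation_conditionally_optimal(self, f1):
        # with hydrogen transfer limited to 5, the allocation-conditional
        # optimum for both members is 5: no gap against the realized fluxes
        from comfba import ConstraintSpec, solve_descriptive

        com, _ = f1
        sol = solve_descriptive(
            com, experimental=[ConstraintSpec.fixed_flux("biomass:A", 5.0)]
        )
        gaps = certify(sol, com)
        assert gaps == pytest.approx({"A": 0.0, "B": 0.0}, abs=1e-6)

    def test_hand_degraded_solution_shows_its_gap(self, f1):
        com, _ = f1
        sol = copy.deepcopy(solve_predictive(com))
        sol.fluxes["A"].objective = 4.0  # pretend A grew at 4 under flows for 10
        gaps = certify(sol, com)
        assert gaps["A"] == pytest.approx(6.0, abs=1e-6)
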