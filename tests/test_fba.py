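"""Single-species LP core: FBA, allocation-conditional optima, FVA."""

import math

import numpy as np
import pytest

from comfba import (
    InfeasibleError,
    UnboundedError,
    inner_optimum,
    solve_fba,
    solve_fva,
)
from comfba.model import Metabolite, Reaction, SpeciesModel


class TestSolveFBA:
    def test_syntroph_alone_grows_at_substrate_cap(self, species_a):
        # shared metabolites are boundary in isolation: H2 and by-product
        # export are unrestricted, substrate transport capped at 10
        sol = solve_fba(species_a)
        assert sol.objective == pytest.approx(10.0, abs=1e-9)
        assert sol["tS"] == pytest.approx(10.0, abs=1e-9)

    def test_blocking_hydrogen_export_blocks_growth(self, species_a):
        # fermentation is growth-coupled to H2 evolution: closing the H2
        # transporter blocks the whole pathway
        sol = solve_fba(species_a, overrides={"tH": (0.0, 0.0)})
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_all_exchanges_closed_means_zero_growth(self, species_a):
        shared = set(species_a.shared_ids)
        overrides = {
            r.id: (0.0, 0.0)
            for r in species_a.reactions
            if r.is_exchange(shared)
        }
        assert solve_fba(species_a, overrides).objective == pytest.approx(0.0)

    def test_steady_state_and_bounds_hold(self, species_b):
        sol = solve_fba(species_b)
        S = species_b.stoichiometric_matrix()
        v = np.array([sol[r.id] for r in species_b.reactions])
        internal = [i for i, m in enumerate(species_b.metabolites) if not m.shared]
        assert np.max(np.abs(S[internal] @ v)) <= 1e-9
        lb, ub = species_b.bounds_arrays()
        assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)

    def test_unbounded_biomass_names_a_ray_member(self):
        m = SpeciesModel(
            "x", [Metabolite("s", shared=True), Metabolite("c")],
            [
                Reaction("t", {"s": -1, "c": 1}, 0, math.inf),
                Reaction("bio", {"c": -1}, 0, math.inf, is_biomass=True),
            ],
        )
        with pytest.raises(UnboundedError) as err:
            solve_fba(m)
        assert err.value.ray_member in ("t", "bio")

    def test_contradictory_bounds_are_infeasible(self, species_a):
        with pytest.raises(InfeasibleError):
            solve_fba(species_a, overrides={"tS": (5.0, 5.0), "tH": (0.0, 1.0)})


class TestInnerOptimum:
    def test_methanogen_grows_one_to_one_on_hydrogen(self, species_b):
        assert inner_optimum(species_b, {"Hx": (10.0, 0.0)}) == pytest.approx(10.0)

    def test_no_hydrogen_no_growth(self, species_b):
        assert inner_optimum(species_b, {"Hx": (0.0, 0.0)}) == pytest.approx(0.0)

    def test_negative_allocation_rejected(self, species_b):
        with pytest.raises(ValueError):
            inner_optimum(species_b, {"Hx": (-1.0, 0.0)})

    def test_unknown_metabolite_rejected(self, species_b):
        with pytest.raises(KeyError):
            inner_optimum(species_b, {"Xx": (1.0, 0.0)})

    def test_infeasible_allocation_is_marked_not_zero(self, species_a):
        # exporting H2 without substrate supply is stoichiometrically impossible
        marker = inner_optimum(species_a, {"Sx": (0.0, 0.0), "Hx": (0.0, 5.0)})
        assert marker is None

    def test_concavity_in_the_allocation(self, species_b):
        # the allocation-conditional optimum is a concave piecewise-linear
        # function of the assigned flows
        rng = np.random.default_rng(42)
        for _ in range(20):
            u1, u2 = rng.uniform(0, 20, size=2)  # within transport capacity
            lam = rng.uniform()
            z1 = inner_optimum(species_b, {"Hx": (u1, 0.0)})
            z2 = inner_optimum(species_b, {"Hx": (u2, 0.0)})
            zm = inner_optimum(species_b, {"Hx": (lam * u1 + (1 - lam) * u2, 0.0)})
            assert zm >= lam * z1 + (1 - lam) * z2 - 1e-7


class TestFVA:
    def test_hydrogen_export_forced_at_optimum(self, species_a):
        assert solve_fva(species_a, ["tH"], 1.0)["tH"] == pytest.approx((10.0, 10.0))

    def test_hydrogen_export_free_at_zero_fraction(self, species_a):
        assert solve_fva(species_a, ["tH"], 0.0)["tH"] == pytest.approx((0.0, 10.0))

    def test_empty_target_list(self, species_a):
        assert solve_fva(species_a, [], 1.0) == {}

    def test_fva_brackets_the_optimal_flux(self, species_a, species_b):
        for m in (species_a, species_b):
            sol = solve_fba(m)
            ranges = solve_fva(m, m.reaction_ids, 1.0)
            for rid, (lo, hi) in ranges.items():
                assert lo - 1e-7 <= sol[rid] <= hi + 1e-7

    def test_fraction_out_of_range_rejected(self, species_a):
        with pytest.raises(ValueError):
            solve_fva(species_a, ["tH"], 1.5)


class TestAgainstCOBRA:
    def test_fba_matches_cobrapy_on_the_syntroph(self, species_a):
        """Independent cross-check with an established FBA implementation."""
        cobra = pytest.importorskip("cobra")
        model = cobra.Model("A")
        shared = set(species_a.shared_ids)
        mets = {
            m.id: cobra.Metabolite(m.id)
            for m in species_a.metabolites if not m.shared
        }
        for r in species_a.reactions:
            rx = cobra.Reaction(r.id, lower_bound=r.lb,
                                upper_bound=min(r.ub, 1e6))
            model.add_reactions([rx])
            rx.add_metabolites({
                mets[mid]: coef for mid, coef in r.stoichiometry.items()
                if mid not in shared
            })
        model.objective = species_a.biomass_id
        reference = model.optimize()
        assert reference.status == "optimal"
        assert solve_fba(species_a).objective == pytest.approx(
            reference.objective_value, abs=1e-6
        )
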