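"""Model parsing, validation, and solution serialization."""

import io
import json
import math

import numpy as np
import pytest

from comfba import (
    ModelError,
    ModelFormatError,
    Metabolite,
    Reaction,
    SpeciesModel,
    dump_model_json,
    parse_model,
    read_solution,
    solve_predictive,
    validate_model,
    write_solution,
)
from conftest import sbml_from_species


class TestJSONDialect:
    def test_round_trip_preserves_all_fields(self, species_a):
        text = dump_model_json(species_a)
        back = parse_model(io.StringIO(text), dialect="json")
        assert back.species_id == species_a.species_id
        assert back.metabolites == species_a.metabolites
        assert back.reactions == species_a.reactions

    def test_fixture_species_a_shape(self, species_a):
        assert len(species_a.reactions) == 5
        assert species_a.biomass_id == "bioA"
        assert sorted(species_a.shared_ids) == ["Bx", "Hx", "Sx"]

    def test_null_bounds_mean_unbounded(self):
        doc = {
            "species_id": "x",
            "metabolites": [{"id": "m", "shared": False}],
            "reactions": [
                {"id": "r", "stoich": {"m": 1}, "lb": None, "ub": None, "biomass": True}
            ],
        }
        m = parse_model(io.StringIO(json.dumps(doc)), dialect="json")
        assert m.reactions[0].lb == -math.inf
        assert m.reactions[0].ub == math.inf

    def test_malformed_json_is_format_error(self):
        with pytest.raises(ModelFormatError):
            parse_model(io.StringIO("{not json"), dialect="json")

    def test_missing_field_names_offender(self):
        doc = {"species_id": "x", "metabolites": [], "reactions": [{"id": "r"}]}
        with pytest.raises(ModelFormatError, match="stoich"):
            parse_model(io.StringIO(json.dumps(doc)), dialect="json")


class TestStructuralInvariants:
    def test_empty_reaction_list_rejected(self):
        with pytest.raises(ModelError, match="no reactions"):
            SpeciesModel("x", [Metabolite("m")], [])

    def test_exactly_one_biomass_required(self):
        mets = [Metabolite("m")]
        rxns = [
            Reaction("r1", {"m": -1}, is_biomass=True),
            Reaction("r2", {"m": 1}, is_biomass=True),
        ]
        with pytest.raises(ModelError, match="exactly one biomass"):
            SpeciesModel("x", mets, rxns)

    def test_undeclared_metabolite_rejected(self):
        with pytest.raises(ModelError, match="undeclared"):
            SpeciesModel("x", [Metabolite("m")],
                         [Reaction("r", {"ghost": 1}, is_biomass=True)])


class TestSBML:
    def test_sbml_and_json_agree_on_stoichiometry(self, species_a):
        text = sbml_from_species(species_a)
        back = parse_model(io.StringIO(text), dialect="sbml")
        assert back.species_id == species_a.species_id
        assert [m.id for m in back.metabolites] == [m.id for m in species_a.metabolites]
        assert [m.shared for m in back.metabolites] == [m.shared for m in species_a.metabolites]
        np.testing.assert_array_equal(
            back.stoichiometric_matrix(), species_a.stoichiometric_matrix()
        )
        assert back.biomass_id == species_a.biomass_id
        np.testing.assert_array_equal(back.bounds_arrays()[0], species_a.bounds_arrays()[0])
        np.testing.assert_array_equal(back.bounds_arrays()[1], species_a.bounds_arrays()[1])

    def test_two_flux_objectives_is_ambiguous_biomass(self, species_a):
        text = sbml_from_species(species_a, extra_objective="tS")
        with pytest.raises(ModelError, match="exactly one flux objective"):
            parse_model(io.StringIO(text), dialect="sbml")

    def test_garbage_is_format_error(self):
        with pytest.raises((ModelFormatError, ModelError)):
            parse_model(io.StringIO("<sbml>nope"), dialect="sbml")


class TestValidation:
    def test_fixture_species_are_clean(self, f1, f2, chain):
        for com, _ in (f1, f2, chain):
            for s in com.species:
                assert validate_model(s).ok, s.species_id

    def test_bound_violation_reported(self):
        m = SpeciesModel(
            "x", [Metabolite("a")],
            [Reaction("r", {"a": -1}, lb=2.0, ub=1.0, is_biomass=True)],
        )
        report = validate_model(m)
        kinds = [i.kind for i in report.issues]
        assert kinds == ["bound_violation"]

    def test_blocked_biomass_reported(self):
        # biomass precursor produced by nothing
        m = SpeciesModel(
            "x", [Metabolite("pre"), Metabolite("s", shared=True)],
            [
                Reaction("t", {"s": -1}, 0, 10),  # dead-end uptake
                Reaction("bio", {"pre": -1}, 0, math.inf, is_biomass=True),
            ],
        )
        report = validate_model(m)
        assert any(i.kind == "blocked_biomass" for i in report.issues)

    def test_dangling_metabolite_reported(self):
        m = SpeciesModel(
            "x", [Metabolite("a"), Metabolite("unused")],
            [Reaction("bio", {"a": -1}, 0, 1, is_biomass=True)],
        )
        assert any(i.kind == "dangling_metabolite" and i.subject == "unused"
                   for i in validate_model(m).issues)


class TestSolutionIO:
    def test_tsv_contains_flux_rows_and_preamble(self, f1, tmp_path):
        com, _ = f1
        sol = solve_predictive(com)
        path = tmp_path / "sol.tsv"
        write_solution(sol, path, "tsv")
        text = path.read_text()
        assert "A\tbioA\t10.0" in text
        assert "# objective\t20.0" in text
        assert "# status\toptimal" in text

    @pytest.mark.parametrize("fmt", ["tsv", "json"])
    def test_round_trip_preserves_numerics(self, f1, tmp_path, fmt):
        com, _ = f1
        sol = solve_predictive(com)
        path = tmp_path / f"sol.{fmt}"
        write_solution(sol, path, fmt)
        back = read_solution(path, fmt)
        assert back.status == sol.status
        assert back.objective == sol.objective
        for k in sol.fluxes:
            for rid, v in sol.fluxes[k].values.items():
                assert back.fluxes[k].values[rid] == v
            assert back.uptake[k] == sol.uptake[k]
            assert back.export[k] == sol.export[k]
        assert back.medium_uptake == sol.medium_uptake
        assert back.pool_accumulation == sol.pool_accumulation

    def test_json_round_trip_identity(self, f1, tmp_path):
        com, _ = f1
        sol = solve_predictive(com)
        path = tmp_path / "sol.json"
        write_solution(sol, path, "json")
        back = read_solution(path)
        assert back.fluxes == sol.fluxes
        assert back.c == sol.c
        assert back.inner_gaps == sol.inner_gaps

    def test_infeasible_solution_has_status_and_no_rows(self, tmp_path):
        from comfba.multilevel import CommunitySolution

        sol = CommunitySolution(status="infeasible", mode="predictive",
                                method="dual_milp", meta={"message": "no carbon"})
        path = tmp_path / "sol.tsv"
        write_solution(sol, path, "tsv")
        lines = path.read_text().splitlines()
        assert "# status\tinfeasible" in lines
        assert all(l.startswith("#") or l == "species\treaction\tflux" for l in lines)
        back = read_solution(path, "tsv")
        assert back.status == "infeasible"
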