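"""Reading and writing: species models, community configs, solutions.

Two model dialects are supported. The JSON dialect is canonical for this
package::

    {"species_id": "A",
     "metabolites": [{"id": "Sx", "name": "", "shared": true}, ...],
     "reactions":   [{"id": "tS", "stoich": {"Sx": -1, "Sa": 1},
                      "lb": 0, "ub": 10, "biomass": false}, ...]}

(``ub``/``lb`` of ``null`` mean unbounded on that side; ``biomass`` and
``shared`` default to false.) SBML Level 3 + FBC is read-only: flux bounds
come from the FBC bound parameters, the biomass reaction from the active
FBC objective (exactly one flux objective required), and shared-pool
membership from boundary-condition species or a declared boundary
compartment.

Solutions are written as TSV (one row per flux/flow, ``#`` preamble with
status, objective, optimality levels, duality gaps) or as JSON (full nested
structure); write -> read round-trips preserve all numerics exactly.
"""

from __future__ import annotations

import json
import math
import os
from typing import Any

import yaml

from .community import (
    CommunityModel,
    ConstraintSpec,
    InteractionRule,
    InteractionSpec,
    add_constraint,
    apply_interaction,
    build_community,
)
from .errors import ConfigurationError, ModelError, ModelFormatError
from .fba import FluxVector
from .model import Metabolite, Reaction, SpeciesModel

__all__ = [
    "parse_model",
    "dump_model_json",
    "write_model_json",
    "write_solution",
    "read_solution",
    "load_community",
    "dump_community_yaml",
]


def _to_bound(value, default: float) -> float:
    if value is None:
        return default
    return float(value)


def _from_bound(value: float):
    return None if math.isinf(value) else value


# ---------------------------------------------------------------------------
# model parsing
# ---------------------------------------------------------------------------
def parse_model(source, dialect: str | None = None, **kwargs) -> SpeciesModel:
    """Parse a species model from a path or stream.

    ``dialect`` is "json" or "sbml"; inferred from the file extension when
    omitted (.json -> json, .xml/.sbml -> sbml).
    """
    path = os.fspath(source) if isinstance(source, (str, os.PathLike)) else None
    if dialect is None:
        if path is None:
            raise ConfigurationError("dialect required when parsing from a stream")
        ext = os.path.splitext(path)[1].lower()
        dialect = {"json": "json", ".json": "json", ".xml": "sbml", ".sbml": "sbml"}.get(
            ext
        )
        if dialect is None:
            raise ConfigurationError(f"cannot infer model dialect from '{path}'")
    if dialect == "json":
        return _parse_json(source, path)
    if dialect == "sbml":
        return _parse_sbml(source, path, **kwargs)
    raise ConfigurationError(f"unknown model dialect '{dialect}'")


def _parse_json(source, path) -> SpeciesModel:
    try:
        if path is not None:
            with open(path) as fh:
                doc = json.load(fh)
        else:
            doc = json.load(source)
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"cannot read JSON model: {exc}") from exc
    try:
        mets = [
            Metabolite(m["id"], m.get("name", ""), bool(m.get("shared", False)))
            for m in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                r["id"],
                {str(k): float(v) for k, v in r["stoich"].items()},
                lb=_to_bound(r.get("lb", 0.0), -math.inf),
                ub=_to_bound(r.get("ub"), math.inf),
                is_biomass=bool(r.get("biomass", False)),
            )
            for r in doc["reactions"]
        ]
        sid = doc["species_id"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed JSON model element: {exc!r}") from exc
    return SpeciesModel(sid, mets, rxns)  # structural validation in constructor


_BOUNDARY_COMPARTMENTS = {"e", "ext", "external", "pool", "shared", "boundary"}


def _parse_sbml(source, path, shared_compartments=None) -> SpeciesModel:
    import libsbml

    shared_compartments = set(shared_compartments or _BOUNDARY_COMPARTMENTS)
    if path is not None:
        doc = libsbml.readSBMLFromFile(path)
    else:
        doc = libsbml.readSBMLFromString(source.read())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError("SBML document contains no model")

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        shared = bool(sp.getBoundaryCondition()) or (
            sp.getCompartment() in shared_compartments
        )
        mets.append(Metabolite(sp.getId(), sp.getName() or "", shared))

    fbc = sbml_model.getPlugin("fbc")
    objective_rxns: list[str] = []
    if fbc is not None and fbc.getNumObjectives() > 0:
        objective = fbc.getActiveObjective() or fbc.getObjective(0)
        for j in range(objective.getNumFluxObjectives()):
            objective_rxns.append(objective.getFluxObjective(j).getReaction())
    if len(objective_rxns) != 1:
        raise ModelError(
            f"SBML model must declare exactly one flux objective (biomass), "
            f"found {len(objective_rxns)}: {objective_rxns}"
        )

    def bound_value(pid: str | None, default: float) -> float:
        if not pid:
            return default
        par = sbml_model.getParameter(pid)
        if par is None:
            raise ModelFormatError(f"flux bound parameter '{pid}' not found")
        return par.getValue()

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rfbc = r.getPlugin("fbc")
        default_lb = -math.inf if r.getReversible() else 0.0
        lb = bound_value(rfbc.getLowerFluxBound() if rfbc else None, default_lb)
        ub = bound_value(rfbc.getUpperFluxBound() if rfbc else None, math.inf)
        rxns.append(Reaction(r.getId(), stoich, lb=lb, ub=ub,
                             is_biomass=r.getId() == objective_rxns[0]))
    name = sbml_model.getId() or sbml_model.getName()
    if not name:
        raise ModelFormatError("SBML model has no id to use as species_id")
    return SpeciesModel(name, mets, rxns)


# ---------------------------------------------------------------------------
# model writing (JSON dialect only; SBML writing is out of scope)
# ---------------------------------------------------------------------------
def dump_model_json(m: SpeciesModel) -> str:
    doc = {
        "species_id": m.species_id,
        "metabolites": [
            {"id": x.id, "name": x.name, "shared": x.shared} for x in m.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": {k: v for k, v in r.stoichiometry.items()},
                "lb": _from_bound(r.lb) if r.lb != 0.0 else 0.0,
                "ub": _from_bound(r.ub),
                "biomass": r.is_biomass,
            }
            for r in m.reactions
        ],
    }
    return json.dumps(doc, indent=1)


def write_model_json(m: SpeciesModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(dump_model_json(m))
        fh.write("\n")


# ---------------------------------------------------------------------------
# solutions
# ---------------------------------------------------------------------------
def _solution_dict(sol) -> dict[str, Any]:
    return {
        "status": sol.status,
        "mode": sol.mode,
        "method": sol.method,
        "objective": sol.objective,
        "fluxes": {
            k: {"values": fv.values, "objective": fv.objective}
            for k, fv in sol.fluxes.items()
        },
        "uptake": sol.uptake,
        "export": sol.export,
        "medium_uptake": sol.medium_uptake,
        "pool_accumulation": sol.pool_accumulation,
        "c": sol.c,
        "v_max": sol.v_max,
        "inner_gaps": sol.inner_gaps,
        "meta": sol.meta,
    }


def write_solution(sol, path, fmt: str = "tsv") -> None:
    """Write a community solution as TSV or JSON.

    Infeasible/unbounded solutions carry their status and diagnostics but no
    flux rows. Numbers are written in shortest round-trip representation, so
    write -> read preserves all numerics exactly.
    """
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_solution_dict(sol), fh, indent=1)
            fh.write("\n")
        return
    if fmt != "tsv":
        raise ConfigurationError(f"unknown solution format '{fmt}'")
    lines = [
        f"# status\t{sol.status}",
        f"# mode\t{sol.mode}",
        f"# method\t{sol.method}",
        f"# objective\t{sol.objective!r}",
    ]
    for k in sol.fluxes:
        lines.append(
            "# species\t{k}\tc\t{c!r}\tv_max\t{v!r}\tgap\t{g!r}\tbiomass\t{b!r}".format(
                k=k,
                c=sol.c.get(k, math.nan),
                v=sol.v_max.get(k, math.nan),
                g=sol.inner_gaps.get(k, math.nan),
                b=sol.fluxes[k].objective,
            )
        )
    if sol.meta.get("message"):
        lines.append(f"# message\t{sol.meta['message']}")
    lines.append("species\treaction\tflux")
    if sol.status == "optimal":
        for k, fv in sol.fluxes.items():
            for rid, v in fv.values.items():
                lines.append(f"{k}\t{rid}\t{v!r}")
        for k in sol.uptake:
            for i, v in sol.uptake[k].items():
                lines.append(f"{k}\tuptake:{i}\t{v!r}")
            for i, v in sol.export[k].items():
                lines.append(f"{k}\texport:{i}\t{v!r}")
        for i, v in sol.medium_uptake.items():
            lines.append(f"community\tmedium:{i}\t{v!r}")
        for i, v in sol.pool_accumulation.items():
            lines.append(f"community\taccumulation:{i}\t{v!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_solution(path, fmt: str | None = None):
    """Read a solution written by :func:`write_solution`."""
    from .multilevel import CommunitySolution

    if fmt is None:
        fmt = "json" if str(path).endswith(".json") else "tsv"
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        return CommunitySolution(
            status=doc["status"],
            mode=doc["mode"],
            method=doc["method"],
            objective=doc["objective"],
            fluxes={
                k: FluxVector(k, d["values"], d["objective"])
                for k, d in doc["fluxes"].items()
            },
            uptake=doc["uptake"],
            export=doc["export"],
            medium_uptake=doc["medium_uptake"],
            pool_accumulation=doc["pool_accumulation"],
            c=doc["c"],
            v_max=doc["v_max"],
            inner_gaps=doc["inner_gaps"],
            meta=doc.get("meta", {}),
        )
    sol = CommunitySolution(status="unknown", mode="", method="")
    header: dict[str, tuple[float, float, float, float]] = {}
    flux_rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line == "species\treaction\tflux":
                continue
            if line.startswith("#"):
                parts = line[2:].split("\t")
                if parts[0] == "status":
                    sol.status = parts[1]
                elif parts[0] == "mode":
                    sol.mode = parts[1]
                elif parts[0] == "method":
                    sol.method = parts[1]
                elif parts[0] == "objective":
                    sol.objective = None if parts[1] == "None" else float(parts[1])
                elif parts[0] == "message":
                    sol.meta["message"] = parts[1]
                elif parts[0] == "species":
                    kv = dict(zip(parts[2::2], parts[3::2]))
                    header[parts[1]] = (
                        float(kv["c"]), float(kv["v_max"]),
                        float(kv["gap"]), float(kv["biomass"]),
                    )
                continue
            k, rid, val = line.split("\t")
            flux_rows.append((k, rid, float(val)))
    for k, (c, vmax, gap, bio) in header.items():
        if not math.isnan(c):
            sol.c[k] = c
        if not math.isnan(vmax):
            sol.v_max[k] = vmax
        if not math.isnan(gap):
            sol.inner_gaps[k] = gap
        sol.fluxes[k] = FluxVector(k, {}, bio)
        sol.uptake[k] = {}
        sol.export[k] = {}
    for k, rid, val in flux_rows:
        if k == "community":
            kind, mid = rid.split(":", 1)
            (sol.medium_uptake if kind == "medium" else sol.pool_accumulation)[mid] = val
        elif rid.startswith("uptake:"):
            sol.uptake[k][rid.split(":", 1)[1]] = val
        elif rid.startswith("export:"):
            sol.export[k][rid.split(":", 1)[1]] = val
        else:
            sol.fluxes[k].values[rid] = val
    return sol


# ---------------------------------------------------------------------------
# community YAML config
# ---------------------------------------------------------------------------
def _constraint_from_dict(d: dict) -> ConstraintSpec:
    form = d.get("form")
    try:
        if form == "fixed_flux":
            return ConstraintSpec.fixed_flux(d["target"], d["value"],
                                             level=d.get("level", "outer"))
        if form == "flux_ratio":
            return ConstraintSpec.flux_ratio(d["numerator"], d["denominator"],
                                             d["ratio"], level=d.get("level", "inner"))
        if form == "biomass_ratio":
            return ConstraintSpec.biomass_ratio(d["species_num"], d["species_den"],
                                                d["ratio"])
        if form == "bound_override":
            return ConstraintSpec.bound_override(
                d["target"], _to_bound(d.get("lb", 0.0), -math.inf),
                _to_bound(d.get("ub"), math.inf), level=d.get("level", "outer"))
    except KeyError as exc:
        raise ConfigurationError(f"constraint {d}: missing field {exc}") from exc
    raise ConfigurationError(f"unknown constraint form '{form}'")


def constraint_to_dict(spec: ConstraintSpec) -> dict:
    if spec.form == "fixed_flux":
        return {"form": spec.form, "level": spec.level,
                "target": str(spec.target), "value": spec.value}
    if spec.form == "flux_ratio":
        return {"form": spec.form, "level": spec.level,
                "numerator": str(spec.numerator),
                "denominator": str(spec.denominator), "ratio": spec.ratio}
    if spec.form == "biomass_ratio":
        return {"form": spec.form, "species_num": spec.numerator.species,
                "species_den": spec.denominator.species, "ratio": spec.ratio}
    return {"form": spec.form, "level": spec.level, "target": str(spec.target),
            "lb": _from_bound(spec.lb), "ub": _from_bound(spec.ub)}


def load_community(path) -> CommunityModel:
    """Load a community from its YAML config (see README for the schema)."""
    path = os.fspath(path)
    base = os.path.dirname(os.path.abspath(path))
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot read community config '{path}': {exc}") from exc
    if not isinstance(doc, dict) or "species" not in doc:
        raise ConfigurationError(f"community config '{path}' has no 'species' list")
    models = []
    for entry in doc["species"]:
        mpath = entry["path"] if isinstance(entry, dict) else entry
        if not os.path.isabs(mpath):
            mpath = os.path.join(base, mpath)
        if not os.path.exists(mpath):
            raise ConfigurationError(f"species model file not found: '{mpath}'")
        dialect = entry.get("dialect") if isinstance(entry, dict) else None
        models.append(parse_model(mpath, dialect))
    medium = {str(k): float(v) for k, v in (doc.get("medium") or {}).items()}
    acc = {str(k): float(v) for k, v in (doc.get("accumulation") or {}).items()}
    com = build_community(models, medium, acc, shared_ids=doc.get("shared"))
    inter = doc.get("interaction")
    if inter:
        rules = []
        for rd in inter.get("rules", []):
            cost = rd.get("cost")
            rules.append(InteractionRule(
                metabolite=rd["metabolite"],
                producers=frozenset(rd.get("producers", [])),
                consumers=frozenset(rd.get("consumers", [])),
                must_consume_all=bool(rd.get("must_consume_all", False)),
                cost_coupling=(cost["species"], cost["reaction"],
                               float(cost["coef"]), cost["source"]) if cost else None,
            ))
        com = apply_interaction(
            com, InteractionSpec(inter.get("kind", "custom"), tuple(rules))
        )
    for cd in doc.get("constraints") or []:
        com = add_constraint(com, _constraint_from_dict(cd))
    return com


def dump_community_yaml(
    com: CommunityModel, model_paths: dict[str, str]
) -> str:
    """Serialize a community config (model files referenced by path)."""
    doc: dict[str, Any] = {
        "species": [{"path": model_paths[k]} for k in com.species_ids],
        "shared": list(com.shared_ids),
        "medium": {k: float(v) for k, v in com.medium.items()},
        "accumulation": {k: float(v) for k, v in com.accumulation.items()},
    }
    if com.interaction.rules or com.interaction.kind != "neutral":
        rules = []
        for r in com.interaction.rules:
            rd: dict[str, Any] = {
                "metabolite": r.metabolite,
                "producers": sorted(r.producers),
                "consumers": sorted(r.consumers),
            }
            if r.must_consume_all:
                rd["must_consume_all"] = True
            if r.cost_coupling:
                sp, rid, coef, src = r.cost_coupling
                rd["cost"] = {"species": sp, "reaction": rid, "coef": coef, "source": src}
            rules.append(rd)
        doc["interaction"] = {"kind": com.interaction.kind, "rules": rules}
    if com.constraints:
        doc["constraints"] = [constraint_to_dict(s) for s in com.constraints]
    return yaml.safe_dump(doc, sort_keys=False)
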