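"""Shared fixtures: toy communities and a test-only SBML emitter."""

from __future__ import annotations

import math

import pytest

from comfba import FixtureSpec, make_fixture
from comfba.model import SpeciesModel


@pytest.fixture(scope="session")
def f1():
    """Obligate syntrophy pair (known total-biomass optimum 20)."""
    return make_fixture("obligate_syntrophy")


@pytest.fixture(scope="session")
def f2():
    """Two-species substrate competition (known optimum 10)."""
    return make_fixture("competition")


@pytest.fixture(scope="session")
def chain():
    """Three-member commensal chain (optimum via oracle)."""
    return make_fixture("commensal_chain")


@pytest.fixture(scope="session")
def species_a(f1):
    com, _ = f1
    return com.species_by_id("A")


@pytest.fixture(scope="session")
def species_b(f1):
    com, _ = f1
    return com.species_by_id("B")


def random_communities(n: int, start: int = 0):
    return [make_fixture(FixtureSpec("random", seed=s))[0] for s in range(start, start + n)]


def sbml_from_species(m: SpeciesModel, extra_objective: str | None = None) -> str:
    """Emit SBML L3 + FBC for a species model (test instrument only).

    Shared metabolites go to a boundary compartment "e" with
    boundaryCondition set; flux bounds become FBC bound parameters.
    ``extra_objective`` adds a second flux objective (to exercise the
    ambiguous-biomass error path).
    """
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(m.species_id)
    mplug = model.getPlugin("fbc")
    mplug.setStrict(False)
    for cid in ("c", "e"):
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
    for met in m.metabolites:
        s = model.createSpecies()
        s.setId(met.id)
        s.setName(met.name)
        s.setCompartment("e" if met.shared else "c")
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(met.shared)
        s.setConstant(False)

    def add_param(pid: str, value: float) -> None:
        p = model.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)

    for r in m.reactions:
        rx = model.createReaction()
        rx.setId(r.id)
        rx.setFast(False)
        rx.setReversible(r.lb < 0)
        for mid, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        add_param(f"lb_{r.id}", r.lb if math.isfinite(r.lb) else -math.inf)
        add_param(f"ub_{r.id}", r.ub)
        rplug.setLowerFluxBound(f"lb_{r.id}")
        rplug.setUpperFluxBound(f"ub_{r.id}")
    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(m.biomass_id)
    fo.setCoefficient(1.0)
    if extra_objective is not None:
        fo2 = obj.createFluxObjective()
        fo2.setReaction(extra_objective)
        fo2.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")
    return libsbml.writeSBMLToString(doc)
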