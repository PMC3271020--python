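"""Deterministic toy communities with known or oracle-computable optima.

Desk-scale stand-ins for the published genome-scale case studies: a
hydrogen-transferring syntrophic pair, a two-species competition for one
substrate, a three-member commensal chain, and seeded random cross-feeding
communities. Stoichiometric coefficients are small integers so every
optimum can be verified by hand or by exact rational reasoning, and the
zero flux vector is always feasible (a community can always "do nothing").

F1, obligate syntrophy (total-biomass optimum = 2 x substrate bound):
species A ferments substrate Sx, producing hydrogen Ha and by-product Ba in
fixed proportion to growth (rA: Sa -> 2 Ba + Ha + BmA; bioA: BmA ->).
Hydrogen must be exported to the pool (accumulation of Hx is forbidden) and
consumed by methanogen-like species B, whose growth runs 1:1 on hydrogen.
Growth-coupled hydrogen evolution is what makes the pair obligate: neither
member can grow without the other taking/making hydrogen.

F2, competition: two species draw on one substrate pool (medium bound 10);
species "1" converts substrate to biomass at yield 1, species "2" at yield
0.5. The community optimum (10) allocates everything to the better
converter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .community import (
    CommunityModel,
    InteractionRule,
    InteractionSpec,
    apply_interaction,
    build_community,
)
from .errors import ConfigurationError
from .model import Metabolite, Reaction, SpeciesModel

__all__ = ["FixtureSpec", "make_fixture", "TOPOLOGIES"]

TOPOLOGIES = ("obligate_syntrophy", "competition", "commensal_chain", "random")


@dataclass(frozen=True)
class FixtureSpec:
    topology: str
    params: dict = field(default_factory=dict)
    seed: int | None = None


def _met(mid: str, shared: bool = False) -> Metabolite:
    return Metabolite(mid, "", shared)


def _obligate_syntrophy(s_bound: float = 10.0):
    inf = math.inf
    a = SpeciesModel(
        "A",
        [_met("Sx", True), _met("Sa"), _met("Ba"), _met("Ha"), _met("BmA"),
         _met("Hx", True), _met("Bx", True)],
        [
            Reaction("tS", {"Sx": -1, "Sa": 1}, 0, s_bound),
            Reaction("rA", {"Sa": -1, "Ba": 2, "Ha": 1, "BmA": 1}, 0, inf),
            Reaction("tH", {"Ha": -1, "Hx": 1}, 0, inf),
            Reaction("tB", {"Ba": -1, "Bx": 1}, 0, inf),
            Reaction("bioA", {"BmA": -1}, 0, inf, is_biomass=True),
        ],
    )
    b = SpeciesModel(
        "B",
        [_met("Hx", True), _met("Hb"), _met("Mb")],
        [
            Reaction("tHup", {"Hx": -1, "Hb": 1}, 0, 2 * s_bound),
            Reaction("rB", {"Hb": -1, "Mb": 1}, 0, inf),
            Reaction("bioB", {"Mb": -1}, 0, inf, is_biomass=True),
        ],
    )
    com = build_community(
        [a, b], medium={"Sx": s_bound}, accumulation={"Hx": 0.0, "Bx": inf}
    )
    com = apply_interaction(com, InteractionSpec(
        "mutualism",
        (InteractionRule("Hx", producers=frozenset({"A"}),
                         consumers=frozenset({"B"}), must_consume_all=True),),
    ))
    return com, 2.0 * s_bound


def _competition(s_bound: float = 10.0):
    inf = math.inf
    sp1 = SpeciesModel(
        "1",
        [_met("Sx", True), _met("C1")],
        [
            Reaction("t1", {"Sx": -1, "C1": 1}, 0, 2 * s_bound),
            Reaction("bio1", {"C1": -1}, 0, inf, is_biomass=True),
        ],
    )
    sp2 = SpeciesModel(
        "2",
        [_met("Sx", True), _met("C2")],
        [
            Reaction("t2", {"Sx": -1, "C2": 1}, 0, 2 * s_bound),
            Reaction("bio2", {"C2": -2}, 0, inf, is_biomass=True),
        ],
    )
    com = build_community([sp1, sp2], medium={"Sx": s_bound})
    com = apply_interaction(com, InteractionSpec(
        "competition",
        (InteractionRule("Sx", producers=frozenset(),
                         consumers=frozenset({"1", "2"})),),
    ))
    return com, s_bound


def _commensal_chain(s_bound: float = 10.0):
    inf = math.inf
    a = SpeciesModel(
        "A",
        [_met("Sx", True), _met("Ca"), _met("BmA"), _met("Pa"), _met("Px", True)],
        [
            Reaction("tSa", {"Sx": -1, "Ca": 1}, 0, s_bound),
            Reaction("rA", {"Ca": -1, "BmA": 1, "Pa": 1}, 0, inf),
            Reaction("tP", {"Pa": -1, "Px": 1}, 0, inf),
            Reaction("bioA", {"BmA": -1}, 0, inf, is_biomass=True),
        ],
    )
    b = SpeciesModel(
        "B",
        [_met("Px", True), _met("Cb"), _met("BmB"), _met("Qb"), _met("Qx", True)],
        [
            Reaction("tPb", {"Px": -1, "Cb": 1}, 0, 2 * s_bound),
            Reaction("rB", {"Cb": -1, "BmB": 1, "Qb": 1}, 0, inf),
            Reaction("tQ", {"Qb": -1, "Qx": 1}, 0, inf),
            Reaction("bioB", {"BmB": -1}, 0, inf, is_biomass=True),
        ],
    )
    c = SpeciesModel(
        "C",
        [_met("Qx", True), _met("Cc")],
        [
            Reaction("tQc", {"Qx": -1, "Cc": 1}, 0, 2 * s_bound),
            Reaction("bioC", {"Cc": -1}, 0, inf, is_biomass=True),
        ],
    )
    com = build_community([a, b, c], medium={"Sx": s_bound})
    com = apply_interaction(com, InteractionSpec(
        "commensalism",
        (
            InteractionRule("Px", producers=frozenset({"A"}), consumers=frozenset({"B"})),
            InteractionRule("Qx", producers=frozenset({"B"}), consumers=frozenset({"C"})),
        ),
    ))
    return com, None


def _random_community(seed: int):
    """Seeded random cross-feeding community.

    A primary degrader feeds 1 or 2 downstream consumers through a single
    cross-fed metabolite Cx (always present, so the bilevel coupling is
    non-trivial): the degrader's by-product evolution is growth-coupled with
    integer yield, consumers convert Cx to biomass with integer yields and
    finite transport capacities. Identical seeds give identical communities.
    """
    rng = np.random.default_rng(seed)
    inf = math.inf
    n_consumers = int(rng.integers(1, 3))  # 1 or 2 -> 2- or 3-species community
    medium_bound = float(rng.integers(4, 11))
    t1_cap = float(rng.integers(4, 9))
    g1 = int(rng.integers(1, 4))   # degrader biomass yield per substrate
    h1 = int(rng.integers(1, 3))   # by-product yield per substrate

    mets = [_met("Sx", True), _met("S1"), _met("Bm1"), _met("P1"), _met("Cx", True)]
    rxns = [
        Reaction("tS", {"Sx": -1, "S1": 1}, 0, t1_cap),
        Reaction("r1", {"S1": -1, "Bm1": g1, "P1": h1}, 0, inf),
        Reaction("tC", {"P1": -1, "Cx": 1}, 0, inf),
        Reaction("bio1", {"Bm1": -1}, 0, inf, is_biomass=True),
    ]
    if rng.random() < 0.5:  # optional inert detour reaction
        mets.append(_met("X1"))
        rxns.insert(2, Reaction("rX", {"P1": -1, "X1": 1}, 0, 0.0))
    sp1 = SpeciesModel("deg", mets, rxns)

    consumers = []
    for ci in range(n_consumers):
        cap = float(rng.integers(3, 10))
        g = int(rng.integers(1, 4))
        sid = f"con{ci + 1}"
        consumers.append(SpeciesModel(
            sid,
            [_met("Cx", True), _met(f"C{ci}"), _met(f"Bm{ci}")],
            [
                Reaction("tCup", {"Cx": -1, f"C{ci}": 1}, 0, cap),
                Reaction("rC", {f"C{ci}": -1, f"Bm{ci}": g}, 0, inf),
                Reaction(f"bio{sid}", {f"Bm{ci}": -1}, 0, inf, is_biomass=True),
            ],
        ))
    com = build_community(
        [sp1, *consumers],
        medium={"Sx": medium_bound},
        accumulation={"Sx": 0.0, "Cx": 0.0},
    )
    com = apply_interaction(com, InteractionSpec(
        "commensalism",
        (InteractionRule("Cx", producers=frozenset({"deg"}),
                         consumers=frozenset(s.species_id for s in consumers)),),
    ))
    return com, None


def make_fixture(
    spec: FixtureSpec | str, **params
) -> tuple[CommunityModel, float | None]:
    """Build a named toy community.

    Returns ``(community, known_optimum)`` where ``known_optimum`` is the
    exact total-biomass predictive optimum when one is known in closed form,
    else ``None`` (use the grid oracle).
    """
    if isinstance(spec, str):
        spec = FixtureSpec(spec, params)
    if spec.topology == "obligate_syntrophy":
        return _obligate_syntrophy(**spec.params)
    if spec.topology == "competition":
        return _competition(**spec.params)
    if spec.topology == "commensal_chain":
        return _commensal_chain(**spec.params)
    if spec.topology == "random":
        if spec.seed is None and "seed" not in spec.params:
            raise ConfigurationError("random topology requires a seed")
        seed = spec.seed if spec.seed is not None else spec.params["seed"]
        return _random_community(int(seed))
    raise ConfigurationError(
        f"unknown fixture topology '{spec.topology}'; choose from {TOPOLOGIES}"
    )
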