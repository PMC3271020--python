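"""Community assembly: shared-metabolite pool, interaction typing, constraints.

A :class:`CommunityModel` couples per-species models through one pool per
shared metabolite i. Each species k that declares i carries two nonnegative
flow variables, uptake u[k,i] and export e[k,i] (mmol/gDW/h), tied to the
species' own steady state by (S_k v_k)_i = e[k,i] - u[k,i]. The pool itself
is mass balanced against the environment:

    sum_k e[k,i] + u_c[i]  =  sum_k u[k,i] + e_c[i]

with community uptake 0 <= u_c[i] <= medium[i] and accumulation
0 <= e_c[i] <= accumulation[i] (0 forbids accumulation). Uptake and export
are kept as separate nonnegative variables so that interaction types can
restrict directions independently; futile simultaneous uptake+export is
suppressed by the solvers' minimal-exchange tie-break, not by binaries.

Interaction types (mutualism, commensalism, competition, parasitism,
amensalism, ...) are encoded purely by adjusting the admissible directions of
these inter-organism flows, plus — for inhibitory (amensalism/parasitism
cost) arms — a mandatory drain flux in the affected species coupled linearly
to the producer's export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError
from .model import SpeciesModel

__all__ = [
    "FlowRef",
    "parse_flow_ref",
    "ConstraintSpec",
    "InteractionRule",
    "InteractionSpec",
    "CommunityModel",
    "build_community",
    "apply_interaction",
    "add_constraint",
]

INTERACTION_KINDS = {
    "neutral",
    "mutualism",
    "commensalism",
    "amensalism",
    "competition",
    "parasitism",
    "custom",
}


# ---------------------------------------------------------------------------
# flow references
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FlowRef:
    """A reference to a single flux/flow in a community.

    kinds: ``reaction`` (id = reaction id, species required), ``biomass``
    (species required), ``uptake``/``export`` (id = shared metabolite,
    species required), ``medium``/``accumulation`` (id = shared metabolite,
    community-level).
    """

    kind: str
    id: str | None = None
    species: str | None = None

    def __str__(self) -> str:
        if self.kind == "reaction":
            return f"{self.species}:{self.id}"
        if self.kind == "biomass":
            return f"biomass:{self.species}"
        if self.kind in ("uptake", "export"):
            return f"{self.kind}:{self.id}@{self.species}"
        return f"{self.kind}:{self.id}"


def parse_flow_ref(text: str) -> FlowRef:
    """Parse the string form used in YAML configs and the CLI.

    ``"A:rA"`` (reaction rA of species A), ``"biomass:A"``,
    ``"uptake:Hx@B"``, ``"export:Hx@A"``, ``"medium:Sx"``,
    ``"accumulation:Bx"``.
    """
    if ":" not in text:
        raise ConfigurationError(f"cannot parse flow reference '{text}'")
    head, rest = text.split(":", 1)
    if head == "biomass":
        return FlowRef("biomass", species=rest)
    if head in ("uptake", "export"):
        if "@" not in rest:
            raise ConfigurationError(f"'{text}': expected '{head}:<metabolite>@<species>'")
        mid, sp = rest.rsplit("@", 1)
        return FlowRef(head, id=mid, species=sp)
    if head in ("medium", "accumulation"):
        return FlowRef(head, id=rest)
    return FlowRef("reaction", id=rest, species=head)


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ConstraintSpec:
    """An experimental/structural constraint attached to a level.

    forms:
      * ``fixed_flux``      target = value
      * ``flux_ratio``      numerator - ratio * denominator = 0
      * ``biomass_ratio``   bio(species_num) - ratio * bio(species_den) = 0 (outer)
      * ``bound_override``  replace (lb, ub) of target

    ``level`` is "inner" (lives inside one species' optimization problem and
    therefore shapes that species' own optimum) or "outer" (restricts the
    community configuration only). Inner constraints may reference reactions
    of a single species; outer constraints may reference biomass fluxes and
    pool flows.
    """

    form: str
    level: str = "outer"
    target: FlowRef | None = None
    value: float | None = None
    numerator: FlowRef | None = None
    denominator: FlowRef | None = None
    ratio: float | None = None
    lb: float | None = None
    ub: float | None = None
    label: str = ""

    # -- convenience constructors -------------------------------------------
    @staticmethod
    def fixed_flux(target: FlowRef | str, value: float, level: str = "outer",
                   label: str = "") -> "ConstraintSpec":
        t = parse_flow_ref(target) if isinstance(target, str) else target
        return ConstraintSpec("fixed_flux", level, target=t, value=float(value),
                              label=label or f"fixed_flux {t}={value}")

    @staticmethod
    def flux_ratio(numerator: FlowRef | str, denominator: FlowRef | str,
                   ratio: float, level: str = "inner", label: str = "") -> "ConstraintSpec":
        n = parse_flow_ref(numerator) if isinstance(numerator, str) else numerator
        d = parse_flow_ref(denominator) if isinstance(denominator, str) else denominator
        return ConstraintSpec("flux_ratio", level, numerator=n, denominator=d,
                              ratio=float(ratio), label=label or f"flux_ratio {n}={ratio}*{d}")

    @staticmethod
    def biomass_ratio(species_num: str, species_den: str, ratio: float,
                      label: str = "") -> "ConstraintSpec":
        return ConstraintSpec(
            "biomass_ratio", "outer",
            numerator=FlowRef("biomass", species=species_num),
            denominator=FlowRef("biomass", species=species_den),
            ratio=float(ratio),
            label=label or f"biomass_ratio {species_num}/{species_den}={ratio}",
        )

    @staticmethod
    def bound_override(target: FlowRef | str, lb: float, ub: float,
                       level: str = "outer", label: str = "") -> "ConstraintSpec":
        t = parse_flow_ref(target) if isinstance(target, str) else target
        return ConstraintSpec("bound_override", level, target=t, lb=float(lb),
                              ub=float(ub), label=label or f"bound_override {t}=[{lb},{ub}]")

    def refs(self) -> list[FlowRef]:
        return [r for r in (self.target, self.numerator, self.denominator) if r is not None]


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class InteractionRule:
    """Directionality of one shared metabolite's inter-organism flow.

    Species in ``producers`` may export the metabolite, species in
    ``consumers`` may take it up; every other species' corresponding flow is
    pinned to zero. ``must_consume_all`` forbids pool accumulation of the
    metabolite. ``cost_coupling = (species, reaction_id, coef, source)``
    forces the mandatory inhibitory-cost flux
    v[species, reaction] = coef * e[source, metabolite].
    """

    metabolite: str
    producers: frozenset[str] = frozenset()
    consumers: frozenset[str] = frozenset()
    must_consume_all: bool = False
    cost_coupling: tuple[str, str, float, str] | None = None


@dataclass(frozen=True)
class InteractionSpec:
    kind: str = "neutral"
    rules: tuple[InteractionRule, ...] = ()

    def __post_init__(self):
        if self.kind not in INTERACTION_KINDS:
            raise ConfigurationError(f"unknown interaction kind '{self.kind}'")


# ---------------------------------------------------------------------------
# community model
# ---------------------------------------------------------------------------
@dataclass
class CommunityModel:
    species: list[SpeciesModel]
    shared_ids: list[str]
    medium: dict[str, float]        # u_c upper bounds, >= 0
    accumulation: dict[str, float]  # e_c upper bounds, >= 0 (0 forbids)
    interaction: InteractionSpec = field(default_factory=InteractionSpec)
    constraints: list[ConstraintSpec] = field(default_factory=list)

    # -- accessors ------------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    def species_by_id(self, sid: str) -> SpeciesModel:
        for s in self.species:
            if s.species_id == sid:
                return s
        raise KeyError(f"no species '{sid}' in community")

    def touchers(self, met: str) -> list[str]:
        """Species that declare shared metabolite ``met``."""
        return [s.species_id for s in self.species if met in s.shared_ids]

    def flow_pairs(self) -> list[tuple[str, str]]:
        """All (species_id, shared metabolite) pairs carrying u/e variables."""
        return [(k, i) for i in self.shared_ids for k in self.touchers(i)]

    # -- interaction-derived restrictions -------------------------------------
    def effective_flow_bounds(self) -> dict[tuple[str, str], tuple[tuple[float, float], tuple[float, float]]]:
        """((u_lb, u_ub), (e_lb, e_ub)) per (species, metabolite) pair.

        Defaults are [0, +inf) on both; interaction rules pin disallowed
        directions to zero. Recomputed from the interaction spec each time,
        so re-applying the same spec is idempotent.
        """
        inf = math.inf
        fb = {pair: ((0.0, inf), (0.0, inf)) for pair in self.flow_pairs()}
        for rule in self.interaction.rules:
            for k in self.touchers(rule.metabolite):
                u_b, e_b = fb[(k, rule.metabolite)]
                if k not in rule.producers:
                    e_b = (0.0, 0.0)
                if k not in rule.consumers:
                    u_b = (0.0, 0.0)
                fb[(k, rule.metabolite)] = (u_b, e_b)
        return fb

    def effective_accumulation(self) -> dict[str, float]:
        acc = dict(self.accumulation)
        for rule in self.interaction.rules:
            if rule.must_consume_all:
                acc[rule.metabolite] = 0.0
        return acc

    def interaction_constraints(self) -> list[ConstraintSpec]:
        """Outer couplings implied by the interaction (inhibitory-cost arms)."""
        out = []
        for rule in self.interaction.rules:
            if rule.cost_coupling is not None:
                sp, rid, coef, source = rule.cost_coupling
                out.append(ConstraintSpec(
                    "flux_ratio", "outer",
                    numerator=FlowRef("reaction", id=rid, species=sp),
                    denominator=FlowRef("export", id=rule.metabolite, species=source),
                    ratio=float(coef),
                    label=f"inhibitory cost {sp}:{rid} = {coef} * export:{rule.metabolite}@{source}",
                ))
        return out

    # -- reference validation --------------------------------------------------
    def check_ref(self, ref: FlowRef) -> None:
        if ref.kind in ("medium", "accumulation"):
            if ref.id not in self.shared_ids:
                raise ConfigurationError(f"'{ref}': unknown shared metabolite")
            return
        if ref.species not in self.species_ids:
            raise ConfigurationError(f"'{ref}': unknown species '{ref.species}'")
        if ref.kind in ("uptake", "export"):
            if (ref.species, ref.id) not in self.flow_pairs():
                raise ConfigurationError(
                    f"'{ref}': species '{ref.species}' has no pool flow for '{ref.id}'"
                )
        elif ref.kind == "reaction":
            sp = self.species_by_id(ref.species)
            if ref.id not in sp.reaction_ids:
                raise ConfigurationError(f"'{ref}': unknown reaction '{ref.id}'")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def build_community(
    models: list[SpeciesModel],
    medium: dict[str, float] | None = None,
    accumulation: dict[str, float] | None = None,
    shared_ids: list[str] | None = None,
) -> CommunityModel:
    """Assemble species models into a community with a shared-metabolite pool.

    ``medium`` bounds community uptake from the environment per shared
    metabolite; ``accumulation`` bounds what may pile up in the pool.
    Unmentioned shared metabolites default to 0 for both (no external supply,
    no accumulation). Pool flow variables for every (species, shared
    metabolite) pair are created automatically with bounds [0, +inf).
    """
    medium = dict(medium or {})
    accumulation = dict(accumulation or {})
    ids = [m.species_id for m in models]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate species ids: {ids}")
    declared: dict[str, bool] = {}
    for m in models:
        for met in m.metabolites:
            if met.id in declared and declared[met.id] != met.shared:
                raise ConfigurationError(
                    f"metabolite '{met.id}' is shared in one species and internal in another"
                )
            # internal metabolite ids may repeat across species (separate
            # compartments); only shared/internal disagreement for the same id
            # within the shared namespace matters.
            if met.shared:
                declared[met.id] = True
    found = sorted(declared)
    if shared_ids is not None:
        for sid in shared_ids:
            if sid not in found:
                raise ConfigurationError(
                    f"shared metabolite '{sid}' declared in no species model"
                )
        shared = list(shared_ids)
    else:
        shared = found
    for name, mapping in (("medium", medium), ("accumulation", accumulation)):
        for mid, bound in mapping.items():
            if mid not in shared:
                raise ConfigurationError(f"{name} bound for non-shared metabolite '{mid}'")
            if not bound >= 0:
                raise ConfigurationError(f"{name} bound for '{mid}' must be >= 0, got {bound}")
    return CommunityModel(
        species=list(models),
        shared_ids=shared,
        medium=medium,
        accumulation=accumulation,
    )


def apply_interaction(c: CommunityModel, spec: InteractionSpec) -> CommunityModel:
    """Return a community with ``spec`` as its interaction typing.

    The restrictions are derived from the spec on demand, so the operation is
    idempotent and replaces any previously applied interaction.
    """
    for rule in spec.rules:
        if rule.metabolite not in c.shared_ids:
            raise ConfigurationError(
                f"interaction rule references unknown shared metabolite '{rule.metabolite}'"
            )
        for grp in (rule.producers, rule.consumers):
            for sid in grp:
                if sid not in c.species_ids:
                    raise ConfigurationError(
                        f"interaction rule references unknown species '{sid}'"
                    )
        if rule.cost_coupling is not None:
            sp, rid, _, source = rule.cost_coupling
            c.check_ref(FlowRef("reaction", id=rid, species=sp))
            if source not in c.species_ids:
                raise ConfigurationError(f"cost coupling source '{source}' unknown")
    return replace(c, interaction=spec, constraints=list(c.constraints))


def add_constraint(c: CommunityModel, spec: ConstraintSpec) -> CommunityModel:
    """Attach a constraint, validating its references against the community.

    Constraints commute: the feasible set is the intersection of all attached
    constraints regardless of insertion order.
    """
    if spec.form not in ("fixed_flux", "flux_ratio", "biomass_ratio", "bound_override"):
        raise ConfigurationError(f"unknown constraint form '{spec.form}'")
    if spec.level not in ("inner", "outer"):
        raise ConfigurationError(f"unknown constraint level '{spec.level}'")
    refs = spec.refs()
    for ref in refs:
        c.check_ref(ref)
    if spec.level == "inner":
        species = {r.species for r in refs if r.species is not None}
        if len(species) != 1:
            raise ConfigurationError(
                f"inner constraint must reference reactions of exactly one species ({spec.label})"
            )
        if any(r.kind in ("medium", "accumulation") for r in refs):
            raise ConfigurationError(
                f"inner constraint may not reference community-level flows ({spec.label})"
            )
    else:
        for ref in refs:
            if ref.kind == "reaction":
                sp = c.species_by_id(ref.species)
                if ref.id != sp.biomass_id:
                    raise ConfigurationError(
                        "outer constraints may reference biomass fluxes or pool flows "
                        f"only, got reaction '{ref}'"
                    )
    return replace(c, constraints=list(c.constraints) + [spec])
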