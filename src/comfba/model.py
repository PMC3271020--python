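"""Per-species metabolic models.

A :class:`SpeciesModel` is one organism's stoichiometric network: metabolites
(flagged ``shared`` when they belong to the community pool), reactions with
signed stoichiometry and flux bounds (mmol/gDW/h), and exactly one biomass
reaction. Reversible reactions are stored with signed bounds (``lb < 0``);
any splitting into irreversible pairs is a solver-internal matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ModelError

__all__ = [
    "Metabolite",
    "Reaction",
    "SpeciesModel",
    "ValidationIssue",
    "ValidationReport",
    "validate_model",
]


@dataclass(frozen=True)
class Metabolite:
    """A metabolite; ``shared=True`` places it in the community pool.

    Shared metabolites carry the same (case-sensitive) id across every
    species they connect.
    """

    id: str
    name: str = ""
    shared: bool = False


@dataclass
class Reaction:
    """A reaction with stoichiometry ``{metabolite_id: coefficient}``.

    Coefficients are negative for consumed and positive for produced
    metabolites. Bounds are in mmol/gDW/h.
    """

    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = math.inf
    is_biomass: bool = False

    def is_exchange(self, shared_ids: set[str]) -> bool:
        """True when the reaction touches at least one shared metabolite."""
        return any(m in shared_ids for m in self.stoichiometry)


@dataclass
class SpeciesModel:
    species_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]

    # derived indices, built in __post_init__
    _met_index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)
    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._check_structure()
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}

    # -- structural invariants (violations are hard errors, unlike the
    #    report-only issues of validate_model) --------------------------------
    def _check_structure(self) -> None:
        if not self.reactions:
            raise ModelError(f"model '{self.species_id}' has no reactions")
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelError(f"duplicate metabolite ids in '{self.species_id}': {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelError(f"duplicate reaction ids in '{self.species_id}': {dup}")
        declared = set(met_ids)
        biomass = [r.id for r in self.reactions if r.is_biomass]
        if len(biomass) != 1:
            raise ModelError(
                f"model '{self.species_id}' must have exactly one biomass reaction, "
                f"found {len(biomass)}: {biomass}"
            )
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelError(f"reaction '{r.id}' has empty stoichiometry")
            for m, coef in r.stoichiometry.items():
                if m not in declared:
                    raise ModelError(
                        f"reaction '{r.id}' references undeclared metabolite '{m}'"
                    )
                if not math.isfinite(coef):
                    raise ModelError(
                        f"reaction '{r.id}' has non-finite coefficient for '{m}'"
                    )

    # -- accessors ------------------------------------------------------------
    @property
    def biomass_id(self) -> str:
        return next(r.id for r in self.reactions if r.is_biomass)

    @property
    def shared_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.shared]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise KeyError(f"no reaction '{rid}' in species '{self.species_id}'") from None

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions)."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, coef in r.stoichiometry.items():
                S[self._met_index[m], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # "dangling_metabolite" | "bound_violation" | "blocked_biomass"
    subject: str
    detail: str


@dataclass
class ValidationReport:
    species_id: str
    issues: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_model(m: SpeciesModel) -> ValidationReport:
    """Report-only health check of a species model.

    Flags metabolites that appear in no reaction, reactions with ``lb > ub``,
    and a biomass reaction that cannot carry flux even with every exchange
    (shared-metabolite) balance opened to its bounds.
    """
    issues: list[ValidationIssue] = []
    used = {mid for r in m.reactions for mid in r.stoichiometry}
    for met in m.metabolites:
        if met.id not in used:
            issues.append(
                ValidationIssue("dangling_metabolite", met.id, "appears in no reaction")
            )
    for r in m.reactions:
        if r.lb > r.ub:
            issues.append(
                ValidationIssue("bound_violation", r.id, f"lb {r.lb} > ub {r.ub}")
            )
    if not any(i.kind == "bound_violation" for i in issues):
        # local import: fba depends on model
        from .fba import solve_fba

        try:
            sol = solve_fba(m)
            if sol.objective <= 1e-9:
                issues.append(
                    ValidationIssue(
                        "blocked_biomass",
                        m.biomass_id,
                        "biomass flux is zero with all shared exchanges open",
                    )
                )
        except Exception as exc:  # pragma: no cover - defensive
            issues.append(ValidationIssue("blocked_biomass", m.biomass_id, str(exc)))
    return ValidationReport(m.species_id, issues)
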