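"""Single-species LP core: FBA, allocation-conditional optima, and FVA.

The inner problem of the community framework is an ordinary flux balance
analysis LP: maximize the biomass flux v_bio subject to steady state
S v = 0 and bounds lb <= v <= ub. Three variants of the shared-metabolite
(community pool) rows are used:

* *boundary* — shared metabolites have no balance row; exchange reactions
  drain to / draw from an implicit environment. This is plain FBA on the
  species in isolation (:func:`solve_fba`, :func:`solve_fva`).
* *fixed* — the net production of each shared metabolite is pinned to an
  assigned pool allocation, (S v)_i = export_i - uptake_i
  (:func:`inner_optimum`). This is the species' problem "given its flows".
* *ranged* — (S v)_i is confined to an interval; used internally by the
  community solvers and the oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ._backend import LPResult, solve_lp
from .errors import InfeasibleError, UnboundedError
from .model import SpeciesModel

__all__ = ["FluxVector", "solve_fba", "inner_optimum", "solve_fva", "SpeciesLP"]

#: artificial cap used to detect which reaction drives an unbounded objective
_RAY_CAP = 1e9


@dataclass
class FluxVector:
    """An optimal flux distribution for one species."""

    species_id: str
    values: dict[str, float]
    objective: float

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]


class SpeciesLP:
    """Cached matrices for one species' inner LP."""

    def __init__(self, m: SpeciesModel):
        self.model = m
        self.S = m.stoichiometric_matrix()
        self.lb, self.ub = m.bounds_arrays()
        self.rxn_ids = m.reaction_ids
        self.n = len(self.rxn_ids)
        shared = set(m.shared_ids)
        self.shared_ids = [mid for mid in (mm.id for mm in m.metabolites) if mid in shared]
        self.internal_idx = [i for i, mm in enumerate(m.metabolites) if not mm.shared]
        self.shared_idx = {mm.id: i for i, mm in enumerate(m.metabolites) if mm.shared}
        self.biomass_col = self.rxn_ids.index(m.biomass_id)
        self.c_biomass = np.zeros(self.n)
        self.c_biomass[self.biomass_col] = 1.0

    # -- matrix assembly ------------------------------------------------------
    def rows(self, shared_row_bounds: dict[str, tuple[float, float]] | None):
        """Internal steady-state rows plus, optionally, shared-pool rows.

        ``shared_row_bounds`` maps shared-metabolite id -> (lo, hi) bounds on
        the species' net production (S v)_i. ``None`` drops shared rows
        entirely (boundary semantics).
        """
        blocks = [self.S[self.internal_idx, :]]
        lo = [np.zeros(len(self.internal_idx))]
        hi = [np.zeros(len(self.internal_idx))]
        if shared_row_bounds is not None:
            for mid in self.shared_ids:
                lo_i, hi_i = shared_row_bounds.get(mid, (0.0, 0.0))
                blocks.append(self.S[self.shared_idx[mid], :][None, :])
                lo.append(np.array([lo_i]))
                hi.append(np.array([hi_i]))
        A = np.vstack(blocks)
        return sparse.csr_matrix(A), np.concatenate(lo), np.concatenate(hi)

    def effective_bounds(self, overrides=None) -> tuple[np.ndarray, np.ndarray]:
        lb, ub = self.lb.copy(), self.ub.copy()
        for rid, (lo, hi) in (overrides or {}).items():
            j = self.rxn_ids.index(rid) if rid in self.rxn_ids else None
            if j is None:
                raise KeyError(f"override references unknown reaction '{rid}'")
            lb[j], ub[j] = lo, hi
        return lb, ub

    def optimize(
        self,
        shared_row_bounds=None,
        overrides=None,
        objective: np.ndarray | None = None,
        sense: str = "max",
        extra_rows=None,
    ) -> LPResult:
        A, lo, hi = self.rows(shared_row_bounds)
        if extra_rows is not None:
            Ax, lox, hix = extra_rows
            A = sparse.vstack([A, sparse.csr_matrix(np.atleast_2d(Ax))]).tocsr()
            lo = np.concatenate([lo, np.atleast_1d(lox)])
            hi = np.concatenate([hi, np.atleast_1d(hix)])
        lb, ub = self.effective_bounds(overrides)
        c = self.c_biomass if objective is None else objective
        return solve_lp(c, A, lo, hi, lb, ub, sense=sense)


def _name_ray_member(lp: SpeciesLP, overrides) -> str | None:
    """Re-solve with huge finite caps and name a reaction stuck at the cap."""
    lb, ub = lp.effective_bounds(overrides)
    capped = {
        rid: (max(lb[j], -_RAY_CAP), min(ub[j], _RAY_CAP))
        for j, rid in enumerate(lp.rxn_ids)
    }
    res = lp.optimize(shared_row_bounds=None, overrides=capped)
    if not res.optimal or res.x is None:
        return None
    for j, rid in enumerate(lp.rxn_ids):
        if abs(res.x[j]) >= 0.99 * _RAY_CAP and (not math.isfinite(ub[j]) or not math.isfinite(lb[j])):
            return rid
    return None


def solve_fba(
    m: SpeciesModel, overrides: dict[str, tuple[float, float]] | None = None
) -> FluxVector:
    """Plain FBA on a species in isolation (shared metabolites are boundary).

    ``overrides`` replaces (lb, ub) of named reactions for this solve only.
    Raises :class:`UnboundedError` (naming a culprit reaction when one can be
    identified) if the biomass flux is unbounded, and :class:`InfeasibleError`
    if the bounds admit no steady-state flux distribution.
    """
    lp = SpeciesLP(m)
    res = lp.optimize(shared_row_bounds=None, overrides=overrides)
    if res.status == "unbounded":
        member = _name_ray_member(lp, overrides)
        raise UnboundedError(
            f"biomass of '{m.species_id}' is unbounded"
            + (f" (unbounded ray includes '{member}')" if member else ""),
            ray_member=member,
        )
    if res.status == "infeasible":
        raise InfeasibleError(f"FBA on '{m.species_id}' is infeasible under the given bounds")
    return FluxVector(m.species_id, dict(zip(lp.rxn_ids, map(float, res.x))), float(res.objective))


def inner_optimum(
    m: SpeciesModel, allocation: dict[str, tuple[float, float]]
) -> float | None:
    """Maximal biomass of a species with its pool flows fixed to ``allocation``.

    ``allocation`` maps shared-metabolite id -> (uptake, export), both >= 0
    (mmol/gDW/h); shared metabolites not mentioned get (0, 0). Returns the
    optimum, or ``None`` when the allocation is infeasible for the species
    (distinct from a feasible optimum of 0).
    """
    shared = set(m.shared_ids)
    nets: dict[str, tuple[float, float]] = {}
    for mid, (up, ex) in allocation.items():
        if mid not in shared:
            raise KeyError(f"'{mid}' is not a shared metabolite of '{m.species_id}'")
        if up < 0 or ex < 0:
            raise ValueError(f"allocation for '{mid}' must be nonnegative, got ({up}, {ex})")
        net = ex - up
        nets[mid] = (net, net)
    lp = SpeciesLP(m)
    res = lp.optimize(shared_row_bounds=nets)
    if res.status == "infeasible":
        return None
    if res.status == "unbounded":
        raise UnboundedError(f"biomass of '{m.species_id}' unbounded under fixed allocation")
    return float(res.objective)


def solve_fva(
    m: SpeciesModel,
    targets: list[str],
    objective_fraction: float = 1.0,
    overrides: dict[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis on a species in isolation.

    For each target reaction, minimize and maximize its flux subject to
    biomass >= objective_fraction * (FBA optimum).
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    opt = solve_fba(m, overrides=overrides).objective  # raises if infeasible
    lp = SpeciesLP(m)
    floor_row = (lp.c_biomass, objective_fraction * opt, math.inf)
    out: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = lp.rxn_ids.index(rid)
        obj = np.zeros(lp.n)
        obj[j] = 1.0
        lohi = []
        for sense in ("min", "max"):
            res = lp.optimize(
                shared_row_bounds=None,
                overrides=overrides,
                objective=obj,
                sense=sense,
                extra_rows=floor_row,
            )
            if not res.optimal:
                raise InfeasibleError(
                    f"FVA subproblem for '{rid}' returned status {res.status}"
                )
            lohi.append(float(res.objective))
        out[rid] = (lohi[0], lohi[1])
    return out
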