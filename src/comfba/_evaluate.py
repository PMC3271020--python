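"""Inner-optimal responses at a fixed (or interval-bounded) pool allocation.

Given bounds on each species' net pool production, solve every species'
inner biomass LP (including any inner-level constraints attached to the
community), resolve alternate inner optima optimistically with respect to
the outer objective, and assemble a full, pool-balanced community vector.
Used by the grid oracle, by optimality certification, and as the incumbent
generator of the bilinear (spatial branch-and-bound) method.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import sparse

from ._backend import LPResult, solve_lp
from ._program import CommunityProgram

__all__ = ["InnerSolver", "evaluate_allocation"]

_EPS = 1e-9


class InnerSolver:
    """One species' inner LP carved out of a community program.

    The species' rows (steady state, pool links, inner constraints) and
    variable bounds are taken from the program, so inner-level fixed fluxes,
    ratio constraints and bound overrides are all honoured. Pool-link rows
    are re-expressed over the species' own fluxes:
    (S v)_i = net_i, with ``net_i`` supplied per call.
    """

    def __init__(self, program: CommunityProgram, species_id: str):
        self.species_id = species_id
        slp = program.species_lps[species_id]
        self.rxn_ids = slp.rxn_ids
        self.cols = [program.v_col[(species_id, rid)] for rid in slp.rxn_ids]
        self.rows = list(program.species_rows[species_id])
        self.lb = program.var_lb[self.cols].copy()
        self.ub = program.var_ub[self.cols].copy()
        sub = program.A[self.rows, :][:, self.cols]
        self.A = sparse.csr_matrix(sub)
        self.base_lo = program.row_lb[self.rows].copy()
        self.base_hi = program.row_ub[self.rows].copy()
        #: local row index per shared metabolite (pool-link rows)
        self.pool_link_row: dict[str, int] = {}
        for local_r, global_r in enumerate(self.rows):
            label = program.row_labels[global_r]
            if label.startswith(f"{species_id}:pool-link:"):
                self.pool_link_row[label.rsplit(":", 1)[1]] = local_r
        self.biomass_local = self.rxn_ids.index(slp.model.biomass_id)
        self.c_biomass = np.zeros(len(self.cols))
        self.c_biomass[self.biomass_local] = 1.0

    def solve(
        self,
        net_bounds: dict[str, tuple[float, float]],
        objective: np.ndarray | None = None,
        sense: str = "max",
        extra_rows=None,
    ) -> LPResult:
        lo, hi = self.base_lo.copy(), self.base_hi.copy()
        for met, (nlo, nhi) in net_bounds.items():
            r = self.pool_link_row[met]
            lo[r], hi[r] = nlo, nhi
        A = self.A
        if extra_rows is not None:
            Ax, lox, hix = extra_rows
            A = sparse.vstack([A, sparse.csr_matrix(np.atleast_2d(Ax))]).tocsr()
            lo = np.concatenate([lo, np.atleast_1d(lox)])
            hi = np.concatenate([hi, np.atleast_1d(hix)])
        c = self.c_biomass if objective is None else objective
        return solve_lp(c, A, lo, hi, self.lb, self.ub, sense=sense)

    def optimum(self, net_bounds) -> float | None:
        res = self.solve(net_bounds)
        return float(res.objective) if res.optimal else None

    def realized_nets(self, v_local: np.ndarray) -> dict[str, float]:
        out = {}
        for met, r in self.pool_link_row.items():
            out[met] = float(self.A.getrow(r).dot(v_local).item())
        return out


def evaluate_allocation(
    program: CommunityProgram,
    inner_solvers: dict[str, InnerSolver],
    net_bounds: dict[str, dict[str, tuple[float, float]]],
    outer_vec: np.ndarray,
):
    """Inner-optimal community response to a pool allocation.

    ``net_bounds[k][i]`` bounds species k's net production of shared
    metabolite i (a point allocation uses lo == hi). Returns
    ``(objective, x, inner_optima)`` over the program's continuous columns,
    or ``None`` when some species is infeasible under the allocation or the
    realized flows violate pool/flow bounds.

    Alternate inner optima are resolved optimistically: with the biomass
    pinned at its optimum, the species' contribution to the outer objective
    is maximized (only solved when that contribution is not constant).
    """
    com = program.community
    x = np.zeros(program.ncont)
    inner_optima: dict[str, float] = {}
    realized: dict[tuple[str, str], float] = {}
    for k in com.species_ids:
        solver = inner_solvers[k]
        nb = net_bounds.get(k, {})
        res = solver.solve(nb)
        if not res.optimal:
            return None
        z = float(res.objective)
        inner_optima[k] = z
        v = res.x
        obj_k = outer_vec[solver.cols]
        # optimistic tie-break among alternate inner optima
        if np.any(obj_k != 0.0) and not (
            np.count_nonzero(obj_k) == 1 and obj_k[solver.biomass_local] != 0.0
        ):
            pin = (solver.c_biomass, z - _EPS, z + _EPS)
            res2 = solver.solve(nb, objective=obj_k, sense="max", extra_rows=pin)
            if res2.optimal:
                v = res2.x
        x[solver.cols] = v
        for met, net in solver.realized_nets(v).items():
            realized[(k, met)] = net

    # split nets into (uptake, export), respecting directional flow bounds
    fb = com.effective_flow_bounds()
    for (k, i), net in realized.items():
        (ulb, uub), (elb, eub) = fb[(k, i)]
        u = max(-net, 0.0)
        e = max(net, 0.0)
        if u > uub + _EPS or u < ulb - _EPS or e > eub + _EPS or e < elb - _EPS:
            return None
        x[program.u_col[(k, i)]] = min(max(u, ulb), uub)
        x[program.e_col[(k, i)]] = min(max(e, elb), eub)
    acc = com.effective_accumulation()
    for i in com.shared_ids:
        total = sum(realized.get((k, i), 0.0) for k in com.touchers(i))
        d = -total  # u_c - e_c
        med_i = com.medium.get(i, 0.0)
        acc_i = acc.get(i, 0.0)
        if d > med_i + _EPS or -d > acc_i + _EPS:
            return None
        x[program.uc_col[i]] = min(max(d, 0.0), med_i)
        x[program.ec_col[i]] = min(max(-d, 0.0), acc_i)
    # outer-level constraint rows must hold as well
    for r, label in program.constraint_rows.items():
        if label and r < program.A.shape[0]:
            val = float(program.A.getrow(r).dot(x).item())
            if val < program.row_lb[r] - 1e-7 or val > program.row_ub[r] + 1e-7:
                return None
    return float(outer_vec[: program.ncont].dot(x)), x, inner_optima
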