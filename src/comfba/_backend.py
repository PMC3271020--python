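"""Thin LP/MILP layer over scipy's HiGHS interfaces.

Every optimization in the package goes through :func:`solve_lp` /
:func:`solve_milp`, so a different engine can be plugged in by reimplementing
these two functions. Rows are ranged constraints ``row_lb <= A x <= row_ub``;
equalities are rows with ``row_lb == row_ub``. ``sense`` is "max" or "min".

Default tolerances: primal feasibility 1e-9, dual feasibility/optimality 1e-7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

__all__ = ["LPResult", "solve_lp", "solve_milp"]

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-7

_LP_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": OPTIMALITY_TOL,
}


@dataclass
class LPResult:
    status: str  # optimal | infeasible | unbounded | error
    x: np.ndarray | None = None
    objective: float | None = None
    #: dual value per row (LP only; None for MILP). Sign convention: for a
    #: maximization, the dual of a binding "<= ub" row is >= 0.
    row_duals: np.ndarray | None = None
    message: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


def _as_csr(A) -> sparse.csr_matrix:
    if sparse.issparse(A):
        return A.tocsr()
    return sparse.csr_matrix(np.atleast_2d(np.asarray(A, dtype=float)))


def solve_lp(
    c,
    A,
    row_lb,
    row_ub,
    var_lb,
    var_ub,
    sense: str = "max",
) -> LPResult:
    """Solve a ranged-row LP with HiGHS (via scipy.linprog), returning duals."""
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    n = c.size
    if A is None or getattr(A, "shape", (0,))[0] == 0:
        A = sparse.csr_matrix((0, n))
        row_lb = np.zeros(0)
        row_ub = np.zeros(0)
    A = _as_csr(A)
    row_lb = np.asarray(row_lb, dtype=float)
    row_ub = np.asarray(row_ub, dtype=float)

    eq_mask = row_lb == row_ub
    ub_mask = (~eq_mask) & np.isfinite(row_ub)
    lb_mask = (~eq_mask) & np.isfinite(row_lb)

    A_eq = A[eq_mask] if eq_mask.any() else None
    b_eq = row_lb[eq_mask] if eq_mask.any() else None
    blocks, b_ub_parts = [], []
    if ub_mask.any():
        blocks.append(A[ub_mask])
        b_ub_parts.append(row_ub[ub_mask])
    if lb_mask.any():
        blocks.append(-A[lb_mask])
        b_ub_parts.append(-row_lb[lb_mask])
    A_ub = sparse.vstack(blocks).tocsr() if blocks else None
    b_ub = np.concatenate(b_ub_parts) if b_ub_parts else None

    bounds = list(zip(np.asarray(var_lb, dtype=float), np.asarray(var_ub, dtype=float)))
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options=dict(_LP_OPTIONS),
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return LPResult(status=status, message=res.message)

    # reassemble row duals in the original row order (max-sense convention)
    duals = np.zeros(A.shape[0])
    if A_eq is not None and res.eqlin is not None:
        duals[np.flatnonzero(eq_mask)] = sign * np.asarray(res.eqlin.marginals)
    if A_ub is not None and res.ineqlin is not None:
        marg = sign * np.asarray(res.ineqlin.marginals)
        k = int(ub_mask.sum())
        duals[np.flatnonzero(ub_mask)] += marg[:k]
        duals[np.flatnonzero(lb_mask)] -= marg[k:]
    return LPResult(
        status="optimal",
        x=np.asarray(res.x),
        objective=sign * res.fun,
        row_duals=duals,
    )


def solve_milp(
    c,
    A,
    row_lb,
    row_ub,
    var_lb,
    var_ub,
    integrality,
    sense: str = "max",
    time_limit: float | None = None,
) -> LPResult:
    """Solve a ranged-row MILP with HiGHS (via scipy.optimize.milp)."""
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    n = c.size
    constraints = []
    if A is not None and getattr(A, "shape", (0,))[0]:
        constraints.append(
            LinearConstraint(_as_csr(A), np.asarray(row_lb, float), np.asarray(row_ub, float))
        )
    options: dict = {"mip_rel_gap": 0.0, "presolve": True}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        sign * c,
        constraints=constraints,
        integrality=np.asarray(integrality),
        bounds=Bounds(np.asarray(var_lb, float), np.asarray(var_ub, float)),
        options=options,
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal" or res.x is None:
        return LPResult(status=status if res.x is None else "optimal", message=res.message)
    return LPResult(status="optimal", x=np.asarray(res.x), objective=sign * res.fun)
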