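"""Strong-duality ("bilinear") solution path for predictive mode.

Instead of complementary-slackness binaries, inner optimality of species k
is imposed by the strong-duality equality

    c_k' v_k  =  sum_i lambda_[k,i] * n_[k,i]  +  mu_ub' ub  -  mu_lb' lb

where n_[k,i] = e[k,i] - u[k,i] is the net pool flow entering the inner
right-hand side. The dual-times-flow products make the single-level problem
nonconvex bilinear; it is solved to global optimality by spatial
branch-and-bound: McCormick envelopes relax each product, branching
subdivides the (bounded) net-flow boxes — the envelopes become exact as a
flow box collapses — and incumbents come from fixing the candidate
allocation and re-solving every inner LP (so every incumbent is feasible
and certified by construction).
"""

from __future__ import annotations

import heapq
import itertools
import math

import numpy as np
from scipy import sparse

from ._backend import solve_lp
from ._evaluate import InnerSolver, evaluate_allocation
from ._program import CommunityProgram, _RowBuffer
from .community import CommunityModel
from .errors import ConfigurationError, ConvergenceError

__all__ = ["solve_bilinear"]

_TOL = 1e-6


class _BilinearRelaxation:
    """Static part of the strong-duality program (everything but McCormick)."""

    def __init__(self, program: CommunityProgram, big_m: float):
        self.program = program
        com = program.community
        n = program.ncont
        col = n
        self.lam_col: dict[tuple[str, int], int] = {}
        for k in com.species_ids:
            for r in program.species_rows[k]:
                self.lam_col[(k, r)] = col
                col += 1
        self.mulb_col: dict[int, int] = {}
        self.muub_col: dict[int, int] = {}
        v_cols_of = {
            k: [program.v_col[(k, rid)] for rid in program.species_lps[k].rxn_ids]
            for k in com.species_ids
        }
        for k in com.species_ids:
            for c0 in v_cols_of[k]:
                if math.isfinite(program.var_lb[c0]):
                    self.mulb_col[c0] = col
                    col += 1
                if math.isfinite(program.var_ub[c0]):
                    self.muub_col[c0] = col
                    col += 1
        self.pairs = com.flow_pairs()
        self.n_col: dict[tuple[str, str], int] = {}
        self.p_col: dict[tuple[str, str], int] = {}
        for pair in self.pairs:
            self.n_col[pair] = col
            self.p_col[pair] = col + 1
            col += 2
        self.n_total = col

        var_lb = np.full(col, -math.inf)
        var_ub = np.full(col, math.inf)
        var_lb[:n], var_ub[:n] = program.var_lb, program.var_ub
        for c0 in self.lam_col.values():
            var_lb[c0], var_ub[c0] = -big_m, big_m
        for c0 in itertools.chain(self.mulb_col.values(), self.muub_col.values()):
            var_lb[c0], var_ub[c0] = 0.0, big_m
        self.net_box: dict[tuple[str, str], tuple[float, float]] = {}
        for (k, i) in self.pairs:
            lo, hi = program.net_flow_range(k, i)
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ConfigurationError(
                    f"net flow of '{i}' for '{k}' unbounded; the bilinear method "
                    "needs finite shared-flow ranges (use dual_milp or add bounds)"
                )
            self.net_box[(k, i)] = (lo, hi)
            var_lb[self.n_col[(k, i)]], var_ub[self.n_col[(k, i)]] = lo, hi
        self.var_lb, self.var_ub = var_lb, var_ub
        self.lam_box = (-big_m, big_m)

        buf = _RowBuffer()
        Acsc = program.A.tocsc()
        for k in com.species_ids:
            slp = program.species_lps[k]
            rowset = {r: self.lam_col[(k, r)] for r in program.species_rows[k]}
            bio_col = program.v_col[(k, slp.model.biomass_id)]
            # dual feasibility
            for j, c0 in enumerate(v_cols_of[k]):
                entries: dict[int, float] = {}
                cv = Acsc[:, c0]
                for r, a in zip(cv.indices, cv.data):
                    if r in rowset:
                        entries[rowset[r]] = entries.get(rowset[r], 0.0) + a
                if c0 in self.muub_col:
                    entries[self.muub_col[c0]] = 1.0
                if c0 in self.mulb_col:
                    entries[self.mulb_col[c0]] = entries.get(self.mulb_col[c0], 0.0) - 1.0
                tgt = 1.0 if c0 == bio_col else 0.0
                buf.add(entries, tgt, tgt, f"{k}:dual-feas:{slp.rxn_ids[j]}")
            # strong duality: c'v - sum p - mu_ub'ub + mu_lb'lb = 0
            entries = {bio_col: 1.0}
            for (kk, i) in self.pairs:
                if kk == k:
                    entries[self.p_col[(kk, i)]] = -1.0
            for c0 in v_cols_of[k]:
                if c0 in self.muub_col:
                    entries[self.muub_col[c0]] = entries.get(self.muub_col[c0], 0.0) - program.var_ub[c0]
                if c0 in self.mulb_col:
                    entries[self.mulb_col[c0]] = entries.get(self.mulb_col[c0], 0.0) + program.var_lb[c0]
            buf.add(entries, 0.0, 0.0, f"{k}:strong-duality")
        # net-flow definitions n = e - u
        for (k, i) in self.pairs:
            buf.add({
                self.n_col[(k, i)]: 1.0,
                self.program.e_col[(k, i)]: -1.0,
                self.program.u_col[(k, i)]: 1.0,
            }, 0.0, 0.0, f"netdef:{k}:{i}")
        extra = buf.matrix(col)
        base = sparse.hstack(
            [program.A, sparse.csr_matrix((program.A.shape[0], col - n))]
        ).tocsr()
        self.A_static = sparse.vstack([base, extra]).tocsr()
        self.row_lb = np.concatenate([program.row_lb, np.array(buf.lo)])
        self.row_ub = np.concatenate([program.row_ub, np.array(buf.hi)])

    def solve(self, boxes: dict[tuple[str, str], tuple[float, float]], c_obj):
        """LP relaxation under per-pair net-flow boxes (McCormick per pair)."""
        lam_lo, lam_hi = self.lam_box
        buf = _RowBuffer()
        var_lb = self.var_lb.copy()
        var_ub = self.var_ub.copy()
        for pair, (nlo, nhi) in boxes.items():
            ncol, pcol = self.n_col[pair], self.p_col[pair]
            lcol = None
            # lambda of the pool-link row of this pair
            k, i = pair
            for r in self.program.species_rows[k]:
                if self.program.row_labels[r] == f"{k}:pool-link:{i}":
                    lcol = self.lam_col[(k, r)]
                    break
            var_lb[ncol], var_ub[ncol] = nlo, nhi
            # McCormick envelope of p = lambda * n
            buf.add({pcol: 1.0, ncol: -lam_lo, lcol: -nlo}, -lam_lo * nlo, math.inf, "mc1")
            buf.add({pcol: 1.0, ncol: -lam_hi, lcol: -nhi}, -lam_hi * nhi, math.inf, "mc2")
            buf.add({pcol: 1.0, ncol: -lam_hi, lcol: -nlo}, -math.inf, -lam_hi * nlo, "mc3")
            buf.add({pcol: 1.0, ncol: -lam_lo, lcol: -nhi}, -math.inf, -lam_lo * nhi, "mc4")
        mc = buf.matrix(self.n_total)
        A = sparse.vstack([self.A_static, mc]).tocsr()
        lo = np.concatenate([self.row_lb, np.array(buf.lo)])
        hi = np.concatenate([self.row_ub, np.array(buf.hi)])
        return solve_lp(c_obj, A, lo, hi, var_lb, var_ub, sense="max")


def solve_bilinear(community: CommunityModel, obj, options):
    """Globally solve predictive mode via the strong-duality reformulation."""
    from .multilevel import CommunitySolution, _diagnose_infeasible, _extract, _inner_gaps

    program = CommunityProgram(community)
    relax = _BilinearRelaxation(program, options.big_m)
    inner = {k: InnerSolver(program, k) for k in community.species_ids}
    outer_vec = program.outer_objective_vector(obj)
    c_obj = np.zeros(relax.n_total)
    c_obj[: program.ncont] = outer_vec

    root = dict(relax.net_box)
    res = relax.solve(root, c_obj)
    if res.status == "infeasible":
        return _diagnose_infeasible(program, obj, "predictive", "bilinear")
    if res.status == "unbounded":
        return CommunitySolution(status="unbounded", mode="predictive",
                                 method="bilinear", meta={})

    best_val = -math.inf
    best_x = None
    counter = itertools.count()
    heap = [(-float(res.objective), next(counter), root, res)]
    nodes = 0
    node_cap = 4000
    while heap:
        neg_ub, _, boxes, res = heapq.heappop(heap)
        ub = -neg_ub
        if ub <= best_val + _TOL * max(1.0, abs(best_val)):
            break
        nodes += 1
        if nodes > node_cap:
            raise ConvergenceError(
                f"spatial branch-and-bound exceeded {node_cap} nodes "
                f"(bound gap {ub - best_val:.3g})"
            )
        x = res.x
        # incumbent: fix the candidate allocation, re-solve inner LPs
        nets = {pair: float(x[relax.n_col[pair]]) for pair in relax.pairs}
        net_bounds = {
            k: {i: (nets[(k, i)], nets[(k, i)]) for (kk, i) in relax.pairs if kk == k}
            for k in community.species_ids
        }
        ev = evaluate_allocation(program, inner, net_bounds, outer_vec)
        if ev is not None and ev[0] > best_val:
            best_val, best_x = ev[0], ev[1]
        # violation of each product
        viol = {}
        for pair in relax.pairs:
            k, i = pair
            lcol = None
            for r in program.species_rows[k]:
                if program.row_labels[r] == f"{k}:pool-link:{i}":
                    lcol = relax.lam_col[(k, r)]
                    break
            viol[pair] = abs(x[relax.p_col[pair]] - x[lcol] * x[relax.n_col[pair]])
        worst = max(viol, key=viol.get)
        if viol[worst] <= 1e-7:
            # relaxation is essentially exact here; its value is attainable
            if ev is not None and ub <= best_val + _TOL * max(1.0, abs(best_val)):
                break
        lo, hi = boxes[worst]
        if hi - lo <= 1e-9:
            continue  # box exhausted; bound cannot improve by branching here
        split = min(max(float(x[relax.n_col[worst]]), lo + 0.25 * (hi - lo)),
                    hi - 0.25 * (hi - lo))
        for child_box in ((lo, split), (split, hi)):
            child = dict(boxes)
            child[worst] = child_box
            cres = relax.solve(child, c_obj)
            if cres.optimal and cres.objective > best_val + 1e-12:
                heapq.heappush(heap, (-float(cres.objective), next(counter), child, cres))

    if best_x is None:
        return _diagnose_infeasible(program, obj, "predictive", "bilinear")
    sol = _extract(program, best_x, "predictive", "bilinear", float(best_val),
                   meta={"nodes": nodes})
    sol.inner_gaps = _inner_gaps(program, sol)
    sol.c = {k: 1.0 for k in community.species_ids}
    return sol
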