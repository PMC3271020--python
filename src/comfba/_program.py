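"""Joint community program assembly.

Builds, for one :class:`~comfba.community.CommunityModel`, the continuous
single-level block shared by every solver mode:

* per-species steady state, with shared-metabolite rows
  (S_k v_k)_i - e[k,i] + u[k,i] = 0 linking fluxes to pool flows,
* per-species inner-level constraint rows (flux ratios),
* pool balances  sum_k (e[k,i] - u[k,i]) + u_c[i] - e_c[i] = 0,
* outer-level constraint rows and all variable bounds,

and, on request, the KKT extension that encodes "every species sits at its
own biomass optimum given its pool flows" as mixed-integer constraints:
dual feasibility for each inner LP plus big-M complementary slackness with
indicator binaries. Because the inner right-hand sides (the pool flows)
enter only the primal rows, the extension stays linear in all variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from ._backend import LPResult, solve_lp
from .community import CommunityModel, ConstraintSpec, FlowRef
from .errors import ConfigurationError
from .fba import SpeciesLP

__all__ = ["CommunityProgram", "KKTData"]


class _RowBuffer:
    """COO triplet accumulator for ranged rows."""

    def __init__(self):
        self.rows: list[int] = []
        self.cols: list[int] = []
        self.vals: list[float] = []
        self.lo: list[float] = []
        self.hi: list[float] = []
        self.labels: list[str] = []

    def add(self, entries: dict[int, float], lo: float, hi: float, label: str) -> int:
        r = len(self.lo)
        for c, v in entries.items():
            if v != 0.0:
                self.rows.append(r)
                self.cols.append(c)
                self.vals.append(v)
        self.lo.append(lo)
        self.hi.append(hi)
        self.labels.append(label)
        return r

    def matrix(self, ncols: int) -> sparse.csr_matrix:
        return sparse.coo_matrix(
            (self.vals, (self.rows, self.cols)), shape=(len(self.lo), ncols)
        ).tocsr()


@dataclass
class KKTData:
    """Arrays + bookkeeping for the mixed-integer optimality encoding."""

    A: sparse.csr_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray
    integrality: np.ndarray
    #: columns of dual variables (lambda and mu), for big-M cap validation
    dual_cols: list[int] = field(default_factory=list)
    #: (var_col, side, slack_cap, primal_bound) for slack cap validation
    slack_caps: list[tuple[int, str, float, float]] = field(default_factory=list)
    n_total: int = 0


class CommunityProgram:
    """Index maps and matrices for one community.

    ``extra_constraints`` (e.g. experimental data in descriptive mode) are
    appended to the structural constraints of the community; inner-level
    members reshape the corresponding species' inner problem exactly like
    structural ones.
    """

    def __init__(self, community: CommunityModel,
                 extra_constraints: tuple[ConstraintSpec, ...] = ()):
        self.community = community
        self.constraints = (
            list(community.constraints)
            + community.interaction_constraints()
            + list(extra_constraints)
        )
        self.species_lps = {s.species_id: SpeciesLP(s) for s in community.species}

        # ---- column layout ---------------------------------------------------
        self.v_col: dict[tuple[str, str], int] = {}
        col = 0
        for s in community.species:
            for rid in s.reaction_ids:
                self.v_col[(s.species_id, rid)] = col
                col += 1
        self.u_col: dict[tuple[str, str], int] = {}
        self.e_col: dict[tuple[str, str], int] = {}
        for (k, i) in community.flow_pairs():
            self.u_col[(k, i)] = col
            self.e_col[(k, i)] = col + 1
            col += 2
        self.uc_col: dict[str, int] = {}
        self.ec_col: dict[str, int] = {}
        for i in community.shared_ids:
            self.uc_col[i] = col
            self.ec_col[i] = col + 1
            col += 2
        self.ncont = col

        # ---- variable bounds -------------------------------------------------
        lb = np.zeros(self.ncont)
        ub = np.zeros(self.ncont)
        for s in community.species:
            slp = self.species_lps[s.species_id]
            for j, rid in enumerate(slp.rxn_ids):
                c0 = self.v_col[(s.species_id, rid)]
                lb[c0], ub[c0] = slp.lb[j], slp.ub[j]
        fb = community.effective_flow_bounds()
        for (k, i), ((ulb, uub), (elb, eub)) in fb.items():
            lb[self.u_col[(k, i)]], ub[self.u_col[(k, i)]] = ulb, uub
            lb[self.e_col[(k, i)]], ub[self.e_col[(k, i)]] = elb, eub
        acc = community.effective_accumulation()
        for i in community.shared_ids:
            lb[self.uc_col[i]], ub[self.uc_col[i]] = 0.0, community.medium.get(i, 0.0)
            lb[self.ec_col[i]], ub[self.ec_col[i]] = 0.0, acc.get(i, 0.0)

        # bound-shaping constraints (fixed_flux inner -> pinned variable;
        # bound_override at either level)
        row_constraints: list[ConstraintSpec] = []
        for spec in self.constraints:
            if spec.form == "bound_override":
                c0 = self.ref_col(spec.target)
                lb[c0], ub[c0] = spec.lb, spec.ub
            elif spec.form == "fixed_flux" and spec.level == "inner":
                c0 = self.ref_col(spec.target)
                lb[c0] = ub[c0] = spec.value
            else:
                row_constraints.append(spec)
        self.var_lb, self.var_ub = lb, ub

        # ---- rows ------------------------------------------------------------
        buf = _RowBuffer()
        #: row indices of each species' inner problem (for KKT duals)
        self.species_rows: dict[str, list[int]] = {k: [] for k in community.species_ids}
        for s in community.species:
            k = s.species_id
            slp = self.species_lps[k]
            S = slp.S
            # internal steady state
            for mi in slp.internal_idx:
                entries = {
                    self.v_col[(k, rid)]: S[mi, j]
                    for j, rid in enumerate(slp.rxn_ids) if S[mi, j] != 0.0
                }
                r = buf.add(entries, 0.0, 0.0, f"{k}:balance:{s.metabolites[mi].id}")
                self.species_rows[k].append(r)
            # shared-metabolite rows: (S v)_i - e + u = 0
            for i in slp.shared_ids:
                mi = slp.shared_idx[i]
                entries = {
                    self.v_col[(k, rid)]: S[mi, j]
                    for j, rid in enumerate(slp.rxn_ids) if S[mi, j] != 0.0
                }
                entries[self.u_col[(k, i)]] = entries.get(self.u_col[(k, i)], 0.0) + 1.0
                entries[self.e_col[(k, i)]] = entries.get(self.e_col[(k, i)], 0.0) - 1.0
                r = buf.add(entries, 0.0, 0.0, f"{k}:pool-link:{i}")
                self.species_rows[k].append(r)
        # pool balances
        self.pool_rows: dict[str, int] = {}
        for i in community.shared_ids:
            entries: dict[int, float] = {self.uc_col[i]: 1.0, self.ec_col[i]: -1.0}
            for k in community.touchers(i):
                entries[self.e_col[(k, i)]] = 1.0
                entries[self.u_col[(k, i)]] = -1.0
            self.pool_rows[i] = buf.add(entries, 0.0, 0.0, f"pool:{i}")
        # constraint rows
        self.constraint_rows: dict[int, str] = {}
        for spec in row_constraints:
            entries, lo, hi = self._constraint_row(spec)
            r = buf.add(entries, lo, hi, spec.label)
            self.constraint_rows[r] = spec.label
            if spec.level == "inner":
                sid = next(ref.species for ref in spec.refs() if ref.species)
                self.species_rows[sid].append(r)
        self._buf = buf
        self.A = buf.matrix(self.ncont)
        self.row_lb = np.array(buf.lo)
        self.row_ub = np.array(buf.hi)
        self.row_labels = list(buf.labels)

    # -- reference resolution --------------------------------------------------
    def ref_col(self, ref: FlowRef) -> int:
        com = self.community
        com.check_ref(ref)
        if ref.kind == "reaction":
            return self.v_col[(ref.species, ref.id)]
        if ref.kind == "biomass":
            return self.v_col[(ref.species, com.species_by_id(ref.species).biomass_id)]
        if ref.kind == "uptake":
            return self.u_col[(ref.species, ref.id)]
        if ref.kind == "export":
            return self.e_col[(ref.species, ref.id)]
        if ref.kind == "medium":
            return self.uc_col[ref.id]
        if ref.kind == "accumulation":
            return self.ec_col[ref.id]
        raise ConfigurationError(f"unresolvable reference '{ref}'")

    def ref_vector(self, ref: FlowRef, net: bool = False) -> dict[int, float]:
        """Column->coefficient map for a reference.

        With ``net=True``, uptake/export references denote the *net* flow in
        the named direction (u - e resp. e - u): uptake and export are
        separate nonnegative variables, so the raw variables admit futile
        simultaneous two-way flow which would make objectives/variability on
        them meaningless.
        """
        if net and ref.kind in ("uptake", "export"):
            u = self.u_col[(ref.species, ref.id)]
            e = self.e_col[(ref.species, ref.id)]
            sign = 1.0 if ref.kind == "uptake" else -1.0
            return {u: sign, e: -sign}
        return {self.ref_col(ref): 1.0}

    def _constraint_row(self, spec: ConstraintSpec):
        if spec.form == "fixed_flux":
            return {self.ref_col(spec.target): 1.0}, spec.value, spec.value
        if spec.form in ("flux_ratio", "biomass_ratio"):
            cn = self.ref_col(spec.numerator)
            cd = self.ref_col(spec.denominator)
            entries = {cn: 1.0}
            entries[cd] = entries.get(cd, 0.0) - spec.ratio
            return entries, 0.0, 0.0
        raise ConfigurationError(f"constraint form '{spec.form}' has no row encoding")

    # -- objectives --------------------------------------------------------------
    def outer_objective_vector(self, obj, n: int | None = None) -> np.ndarray:
        """Objective vector over ``n`` columns (default: continuous block)."""
        c = np.zeros(n or self.ncont)
        com = self.community
        if obj.kind in ("total_biomass", "weighted_biomass"):
            weights = obj.weights if obj.kind == "weighted_biomass" else None
            if weights is None:
                weights = {k: 1.0 for k in com.species_ids}
            if not weights or min(weights.values()) < 0 or max(weights.values()) <= 0:
                raise ConfigurationError("weights must be >= 0 with at least one positive")
            for k, w in weights.items():
                c[self.v_col[(k, com.species_by_id(k).biomass_id)]] = w
        elif obj.kind == "single_species":
            c[self.v_col[(obj.species, com.species_by_id(obj.species).biomass_id)]] = 1.0
        elif obj.kind == "target_flux":
            for col, coef in self.ref_vector(obj.target, net=True).items():
                c[col] = coef
        else:
            raise ConfigurationError(f"unknown outer objective kind '{obj.kind}'")
        return c

    # -- continuous solves ---------------------------------------------------------
    def solve_relaxation(self, objective: np.ndarray, sense: str = "max",
                         extra_rows=None) -> LPResult:
        """Solve the single-level relaxation (no inner-optimality coupling)."""
        A, lo, hi = self.A, self.row_lb, self.row_ub
        if extra_rows is not None:
            Ax, lox, hix = extra_rows
            A = sparse.vstack([A, sparse.csr_matrix(np.atleast_2d(Ax))]).tocsr()
            lo = np.concatenate([lo, np.atleast_1d(lox)])
            hi = np.concatenate([hi, np.atleast_1d(hix)])
        return solve_lp(objective, A, lo, hi, self.var_lb, self.var_ub, sense=sense)

    def net_flow_range(self, k: str, i: str) -> tuple[float, float]:
        """Range of the net export e[k,i] - u[k,i] over the relaxation."""
        c = np.zeros(self.ncont)
        c[self.e_col[(k, i)]] = 1.0
        c[self.u_col[(k, i)]] = -1.0
        lo = self.solve_relaxation(c, sense="min")
        hi = self.solve_relaxation(c, sense="max")
        if not (lo.optimal and hi.optimal):
            raise ConfigurationError(
                f"cannot bound net flow of '{i}' for species '{k}' "
                f"(relaxation status {lo.status}/{hi.status})"
            )
        return float(lo.objective), float(hi.objective)

    def diagnose_infeasibility(self, extra_rows=None) -> list[str]:
        """Elastic relaxation: name pool balances / constraint rows that must
        be violated for the continuous block to become feasible."""
        A, lo, hi = self.A, self.row_lb, self.row_ub
        if extra_rows is not None:
            Ax, lox, hix = extra_rows
            A = sparse.vstack([A, sparse.csr_matrix(np.atleast_2d(Ax))]).tocsr()
            lo = np.concatenate([lo, np.atleast_1d(lox)])
            hi = np.concatenate([hi, np.atleast_1d(hix)])
        elastic = sorted(set(self.pool_rows.values()) | set(self.constraint_rows))
        m, n = A.shape
        rows, cols, vals = [], [], []
        for si, r in enumerate(elastic):
            rows.extend([r, r])
            cols.extend([2 * si, 2 * si + 1])
            vals.extend([1.0, -1.0])
        slack_block = sparse.coo_matrix((vals, (rows, cols)), shape=(m, 2 * len(elastic)))
        Aslack = sparse.hstack([A, slack_block]).tocsr()
        c = np.concatenate([np.zeros(n), np.ones(2 * len(elastic))])
        vlb = np.concatenate([self.var_lb, np.zeros(2 * len(elastic))])
        vub = np.concatenate([self.var_ub, np.full(2 * len(elastic), math.inf)])
        res = solve_lp(c, Aslack, lo, hi, vlb, vub, sense="min")
        if not res.optimal:
            return ["(elastic diagnosis unavailable)"]
        labels = self.row_labels + [f"extra:{j}" for j in range(m - len(self.row_labels))]
        out = []
        for si, r in enumerate(elastic):
            s = res.x[n + 2 * si] + res.x[n + 2 * si + 1]
            if s > 1e-6:
                out.append(labels[r] if r < len(labels) else f"row:{r}")
        return out

    # -- KKT / big-M extension ------------------------------------------------------
    def kkt_extension(self, big_m_dual: float = 1e3, big_m_primal: float = 1e3) -> KKTData:
        """Append dual variables, dual feasibility, and complementarity.

        Column layout: [continuous block | per species: lambda, mu_lb, mu_ub |
        per species: binaries]. Binaries are only created for variables with
        a finite, non-degenerate bound on the relevant side.
        """
        com = self.community
        n = self.ncont
        # dual columns
        lam_col: dict[tuple[str, int], int] = {}   # (species, row) -> col
        mulb_col: dict[int, int] = {}              # v col -> col
        muub_col: dict[int, int] = {}
        col = n
        for k in com.species_ids:
            for r in self.species_rows[k]:
                lam_col[(k, r)] = col
                col += 1
        v_cols_of: dict[str, list[int]] = {
            k: [self.v_col[(k, rid)] for rid in self.species_lps[k].rxn_ids]
            for k in com.species_ids
        }
        for k in com.species_ids:
            for c0 in v_cols_of[k]:
                if math.isfinite(self.var_lb[c0]):
                    mulb_col[c0] = col
                    col += 1
                if math.isfinite(self.var_ub[c0]):
                    muub_col[c0] = col
                    col += 1
        ylb_col: dict[int, int] = {}
        yub_col: dict[int, int] = {}
        for k in com.species_ids:
            for c0 in v_cols_of[k]:
                degenerate = self.var_ub[c0] - self.var_lb[c0] <= 0.0
                if c0 in mulb_col and not degenerate:
                    ylb_col[c0] = col
                    col += 1
                if c0 in muub_col and not degenerate:
                    yub_col[c0] = col
                    col += 1
        n_total = col

        var_lb = np.zeros(n_total)
        var_ub = np.zeros(n_total)
        var_lb[:n], var_ub[:n] = self.var_lb, self.var_ub
        integrality = np.zeros(n_total)
        for c0 in lam_col.values():
            var_lb[c0], var_ub[c0] = -big_m_dual, big_m_dual
        for c0 in list(mulb_col.values()) + list(muub_col.values()):
            var_lb[c0], var_ub[c0] = 0.0, big_m_dual
        for c0 in list(ylb_col.values()) + list(yub_col.values()):
            var_lb[c0], var_ub[c0] = 0.0, 1.0
            integrality[c0] = 1.0

        buf = _RowBuffer()
        slack_caps: list[tuple[int, str, float, float]] = []
        Acsc = self.A.tocsc()
        for k in com.species_ids:
            slp = self.species_lps[k]
            rows_k = self.species_rows[k]
            rowset = {r: lam_col[(k, r)] for r in rows_k}
            # dual feasibility: A_k^T lambda + mu_ub - mu_lb = c_biomass
            for j, c0 in enumerate(v_cols_of[k]):
                entries: dict[int, float] = {}
                col_view = Acsc[:, c0]
                for r, a in zip(col_view.indices, col_view.data):
                    if r in rowset:
                        entries[rowset[r]] = entries.get(rowset[r], 0.0) + a
                if c0 in muub_col:
                    entries[muub_col[c0]] = entries.get(muub_col[c0], 0.0) + 1.0
                if c0 in mulb_col:
                    entries[mulb_col[c0]] = entries.get(mulb_col[c0], 0.0) - 1.0
                target = 1.0 if c0 == self.v_col[(k, slp.model.biomass_id)] else 0.0
                buf.add(entries, target, target, f"{k}:dual-feas:{slp.rxn_ids[j]}")
            # complementarity
            for j, c0 in enumerate(v_cols_of[k]):
                lo_b, hi_b = self.var_lb[c0], self.var_ub[c0]
                if c0 in ylb_col:
                    y = ylb_col[c0]
                    buf.add({mulb_col[c0]: 1.0, y: -big_m_dual}, -math.inf, 0.0,
                            f"{k}:cs-mu-lb:{slp.rxn_ids[j]}")
                    cap = min(hi_b - lo_b, big_m_primal)
                    # v - lb <= cap * (1 - y)
                    buf.add({c0: 1.0, y: cap}, -math.inf, lo_b + cap,
                            f"{k}:cs-slack-lb:{slp.rxn_ids[j]}")
                    slack_caps.append((c0, "lb", cap, lo_b))
                if c0 in yub_col:
                    y = yub_col[c0]
                    buf.add({muub_col[c0]: 1.0, y: -big_m_dual}, -math.inf, 0.0,
                            f"{k}:cs-mu-ub:{slp.rxn_ids[j]}")
                    cap = min(hi_b - lo_b, big_m_primal)
                    # ub - v <= cap * (1 - y)
                    buf.add({c0: -1.0, y: cap}, -math.inf, -hi_b + cap,
                            f"{k}:cs-slack-ub:{slp.rxn_ids[j]}")
                    slack_caps.append((c0, "ub", cap, hi_b))

        A_kkt = buf.matrix(n_total)
        base = sparse.hstack(
            [self.A, sparse.csr_matrix((self.A.shape[0], n_total - n))]
        ).tocsr()
        A_full = sparse.vstack([base, A_kkt]).tocsr()
        row_lb = np.concatenate([self.row_lb, np.array(buf.lo)])
        row_ub = np.concatenate([self.row_ub, np.array(buf.hi)])
        dual_cols = (
            list(lam_col.values()) + list(mulb_col.values()) + list(muub_col.values())
        )
        return KKTData(
            A=A_full, row_lb=row_lb, row_ub=row_ub,
            var_lb=var_lb, var_ub=var_ub, integrality=integrality,
            dual_cols=dual_cols, slack_caps=slack_caps, n_total=n_total,
        )

    # -- solution extraction helpers -------------------------------------------------
    def pool_residuals(self, x: np.ndarray) -> dict[str, float]:
        res = {}
        for i, r in self.pool_rows.items():
            res[i] = float(self.A.getrow(r).dot(x[: self.ncont]).item())
        return res
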