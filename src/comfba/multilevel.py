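"""Community-level solvers.

*Predictive mode* answers "what would this community do if every member grew
as fast as its own allocation allows?": maximize a community objective over
inter-organism flow configurations, subject to every species' flux vector
being optimal for its inner biomass LP given its assigned pool flows
(optimistic bilevel semantics). The default solution method encodes inner
optimality through KKT complementary slackness with big-M indicator
binaries, yielding a single MILP; the alternative ``bilinear`` method keeps
the strong-duality equality with its dual-times-flow products and solves it
to global optimality by spatial branch-and-bound.

*Descriptive mode* answers "how close to its own community-specific maximum
does each member grow, given what was measured?": fix experimental
observations as constraints, drop inner optimality, maximize the community
objective, and report each species' optimality level
c_k = v_bio_k / v_bio_k_max against the predictive maxima.

Community flux variability analysis minimizes/maximizes a flux, pool flow,
or flow ratio while keeping the community objective at a fraction of its
optimum and retaining every inner-optimality certificate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from ._backend import solve_milp
from ._evaluate import InnerSolver
from ._program import CommunityProgram
from .community import (
    CommunityModel,
    ConstraintSpec,
    FlowRef,
    add_constraint,
    parse_flow_ref,
)
from .errors import BigMError, ConfigurationError, InfeasibleError
from .fba import FluxVector

log = logging.getLogger(__name__)

__all__ = [
    "OuterObjective",
    "CommunitySolution",
    "SolverOptions",
    "solve_predictive",
    "compute_species_maxima",
    "solve_descriptive",
    "community_fva",
    "run_scenarios",
]

_OPT_EPS = 1e-9          # slack when pinning the outer optimum for tie-breaks
GAP_TOL = 1e-6           # certification tolerance on inner duality gaps


@dataclass(frozen=True)
class OuterObjective:
    """Community-level objective.

    kinds: ``total_biomass`` (sum of biomass fluxes), ``weighted_biomass``
    (nonnegative weights, unit by default), ``single_species`` (one member's
    biomass), ``target_flux`` (any reaction flux or pool flow).
    """

    kind: str = "total_biomass"
    weights: dict[str, float] | None = None
    species: str | None = None
    target: FlowRef | None = None

    @staticmethod
    def total_biomass() -> "OuterObjective":
        return OuterObjective("total_biomass")

    @staticmethod
    def weighted(weights: dict[str, float]) -> "OuterObjective":
        return OuterObjective("weighted_biomass", weights=dict(weights))

    @staticmethod
    def single(species: str) -> "OuterObjective":
        return OuterObjective("single_species", species=species)

    @staticmethod
    def target_flux(target: FlowRef | str) -> "OuterObjective":
        t = parse_flow_ref(target) if isinstance(target, str) else target
        return OuterObjective("target_flux", target=t)


@dataclass
class SolverOptions:
    big_m: float = 1e3          # initial big-M for duals and primal slacks
    max_doublings: int = 3      # certificate failures tolerated before error
    tie_break: bool = True      # secondary minimization of total exchange
    time_limit: float | None = None


@dataclass
class CommunitySolution:
    """A solved (or diagnosed) community configuration."""

    status: str                                  # optimal | infeasible | unbounded | error
    mode: str                                    # predictive | descriptive
    method: str
    objective: float | None = None
    fluxes: dict[str, FluxVector] = field(default_factory=dict)
    uptake: dict[str, dict[str, float]] = field(default_factory=dict)
    export: dict[str, dict[str, float]] = field(default_factory=dict)
    medium_uptake: dict[str, float] = field(default_factory=dict)
    pool_accumulation: dict[str, float] = field(default_factory=dict)
    c: dict[str, float] = field(default_factory=dict)       # optimality levels
    v_max: dict[str, float] = field(default_factory=dict)   # community-specific maxima
    inner_gaps: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def biomass(self, species_id: str) -> float:
        return self.fluxes[species_id].objective

    def net_export(self, species_id: str, met: str) -> float:
        return self.export[species_id][met] - self.uptake[species_id][met]

    def pool_residuals(self) -> dict[str, float]:
        """Conservation residual of each shared-metabolite pool balance."""
        out = {}
        for i in self.medium_uptake:
            total = self.medium_uptake[i] - self.pool_accumulation[i]
            for k, ex in self.export.items():
                if i in ex:
                    total += ex[i] - self.uptake[k][i]
            out[i] = total
        return out


# ---------------------------------------------------------------------------
# shared extraction / certification helpers
# ---------------------------------------------------------------------------
def _extract(program: CommunityProgram, x: np.ndarray, mode: str, method: str,
             objective: float | None, meta: dict | None = None) -> CommunitySolution:
    com = program.community
    fluxes, uptake, export = {}, {}, {}
    for s in com.species:
        k = s.species_id
        vals = {rid: float(x[program.v_col[(k, rid)]]) for rid in s.reaction_ids}
        fluxes[k] = FluxVector(k, vals, vals[s.biomass_id])
        uptake[k] = {}
        export[k] = {}
    for (k, i) in com.flow_pairs():
        uptake[k][i] = float(x[program.u_col[(k, i)]])
        export[k][i] = float(x[program.e_col[(k, i)]])
    return CommunitySolution(
        status="optimal", mode=mode, method=method, objective=objective,
        fluxes=fluxes, uptake=uptake, export=export,
        medium_uptake={i: float(x[program.uc_col[i]]) for i in com.shared_ids},
        pool_accumulation={i: float(x[program.ec_col[i]]) for i in com.shared_ids},
        meta=meta or {},
    )


def _certificate(program: CommunityProgram, sol: CommunitySolution):
    """Independent inner re-solves at the solution's allocation.

    Returns (gaps, max_abs_dual): the allocation-conditional optimum minus
    realized biomass per species, and the largest inner dual multiplier the
    re-solves needed (an unconstrained certificate; it must fit inside the
    big-M box for the MILP encoding to have been unrestricted).
    """
    gaps = {}
    max_dual = 0.0
    for k in program.community.species_ids:
        solver = InnerSolver(program, k)
        # re-solve inside a tiny band around the allocation: the MILP works
        # to ~1e-9 feasibility, the re-solve to 1e-10, so exact pinning
        # would spuriously reject solver round-off
        nets = {}
        for i in sol.uptake[k]:
            net = sol.net_export(k, i)
            band = 1e-8 * max(1.0, abs(net))
            nets[i] = (net - band, net + band)
        res = solver.solve(nets)
        if not res.optimal:
            gaps[k] = math.inf
            continue
        gaps[k] = float(res.objective) - sol.biomass(k)
        if res.row_duals is not None and res.row_duals.size:
            max_dual = max(max_dual, float(np.max(np.abs(res.row_duals))))
    return gaps, max_dual


def _inner_gaps(program: CommunityProgram, sol: CommunitySolution) -> dict[str, float]:
    """Allocation-conditional optimum minus realized biomass, per species."""
    return _certificate(program, sol)[0]


def _flow_cost_vector(program: CommunityProgram, n_total: int) -> np.ndarray:
    c = np.zeros(n_total)
    for col in list(program.u_col.values()) + list(program.e_col.values()):
        c[col] = 1.0
    for col in list(program.uc_col.values()) + list(program.ec_col.values()):
        c[col] = 1.0
    return c


def _caps_ok(kkt, x: np.ndarray, big_m: float) -> bool:
    """No primal slack jammed at an artificial cap.

    The MILP's own dual variables are allowed to sit anywhere on a
    degenerate optimal face, so they are not checked here; the meaningful
    dual-cap test uses the independent re-solves (see :func:`_certificate`).
    """
    for col, side, cap, bound in kkt.slack_caps:
        if side == "lb":
            true_range = kkt.var_ub[col] - bound
            slack = x[col] - bound
        else:
            true_range = bound - kkt.var_lb[col]
            slack = bound - x[col]
        if cap < true_range - 1e-12 and slack >= cap - 1e-7:
            return False
    return True


def _append_row(A, lo, hi, row, rlo, rhi):
    A2 = sparse.vstack([A, sparse.csr_matrix(np.atleast_2d(row))]).tocsr()
    return A2, np.concatenate([lo, [rlo]]), np.concatenate([hi, [rhi]])


# ---------------------------------------------------------------------------
# predictive mode
# ---------------------------------------------------------------------------
def solve_predictive(
    community: CommunityModel,
    obj: OuterObjective | None = None,
    method: str = "dual_milp",
    options: SolverOptions | None = None,
) -> CommunitySolution:
    """Maximize the community objective with every species inner-optimal.

    Returns a :class:`CommunitySolution` whose status is ``optimal``,
    ``infeasible`` or ``unbounded``. Optimal solutions are certified by an
    independent re-solve of every inner LP at the returned allocation
    (``inner_gaps`` <= 1e-6); a failed big-M certificate triggers doubling
    of M, and :class:`BigMError` after ``max_doublings`` failures.
    """
    obj = obj or OuterObjective.total_biomass()
    options = options or SolverOptions()
    if method == "bilinear":
        from ._bilinear import solve_bilinear

        return solve_bilinear(community, obj, options)
    if method != "dual_milp":
        raise ConfigurationError(f"unknown method '{method}'")
    program = CommunityProgram(community)
    return _predictive_milp(program, obj, options)


def _predictive_milp(program: CommunityProgram, obj: OuterObjective,
                     options: SolverOptions) -> CommunitySolution:
    big_m = options.big_m
    for attempt in range(options.max_doublings + 1):
        kkt = program.kkt_extension(big_m, big_m)
        c_outer = program.outer_objective_vector(obj, kkt.n_total)
        res = solve_milp(c_outer, kkt.A, kkt.row_lb, kkt.row_ub,
                         kkt.var_lb, kkt.var_ub, kkt.integrality,
                         sense="max", time_limit=options.time_limit)
        if res.status == "infeasible":
            if attempt < options.max_doublings:
                big_m *= 2.0
                log.info("MILP infeasible at big-M %.3g; doubling", big_m / 2)
                continue
            return _diagnose_infeasible(program, obj, "predictive", "dual_milp")
        if res.status == "unbounded":
            return CommunitySolution(
                status="unbounded", mode="predictive", method="dual_milp",
                meta={"message": "outer objective unbounded over the inner-optimal set"},
            )
        if not res.optimal:
            raise InfeasibleError(f"MILP solver returned status {res.status}: {res.message}")
        opt = float(res.objective)
        x = res.x
        if options.tie_break:
            A2, lo2, hi2 = _append_row(
                kkt.A, kkt.row_lb, kkt.row_ub, c_outer, opt - _OPT_EPS, math.inf
            )
            res2 = solve_milp(
                _flow_cost_vector(program, kkt.n_total), A2, lo2, hi2,
                kkt.var_lb, kkt.var_ub, kkt.integrality, sense="min",
                time_limit=options.time_limit,
            )
            if res2.optimal:
                x = res2.x
        sol = _extract(program, x, "predictive", "dual_milp", opt,
                       meta={"big_m": big_m})
        sol.inner_gaps, max_dual = _certificate(program, sol)
        sol.c = {k: 1.0 for k in program.community.species_ids}
        if (
            _caps_ok(kkt, x, big_m)
            and max_dual < 0.999 * big_m
            and max(sol.inner_gaps.values(), default=0.0) <= GAP_TOL
        ):
            return sol
        big_m *= 2.0
        log.info("big-M certificate failed (gaps %s); doubling to %.3g",
                 sol.inner_gaps, big_m)
    raise BigMError(
        f"big-M certificate still failing after {options.max_doublings} doublings"
    )


def _diagnose_infeasible(program: CommunityProgram, obj: OuterObjective,
                         mode: str, method: str) -> CommunitySolution:
    c_outer = program.outer_objective_vector(obj)
    relax = program.solve_relaxation(c_outer)
    if relax.status == "infeasible":
        violated = program.diagnose_infeasibility()
        msg = "community infeasible; implicated balances/constraints: " + ", ".join(violated)
    else:
        violated = []
        msg = ("no community configuration satisfies every species' "
               "inner-optimality requirement")
    return CommunitySolution(
        status="infeasible", mode=mode, method=method,
        meta={"message": msg, "violated": violated},
    )


# ---------------------------------------------------------------------------
# descriptive mode
# ---------------------------------------------------------------------------
def compute_species_maxima(
    community: CommunityModel,
    obj: OuterObjective | None = None,
    options: SolverOptions | None = None,
    with_ranges: bool = False,
) -> dict[str, float] | tuple[dict[str, float], dict[str, tuple[float, float]]]:
    """Community-specific maximal biomass flux of each species.

    Solved in predictive mode under environmental/structural constraints
    only: each species' maximum is what it attains while all members strive
    to grow maximally. With ``with_ranges=True`` the alternate-optimum range
    of each biomass flux at the fixed outer optimum is reported as well.
    """
    obj = obj or OuterObjective.total_biomass()
    sol = solve_predictive(community, obj, options=options)
    if not sol.optimal:
        raise InfeasibleError(
            f"predictive stage is {sol.status}; species maxima undefined "
            f"({sol.meta.get('message', '')})"
        )
    vmax = {k: sol.biomass(k) for k in community.species_ids}
    if not with_ranges:
        return vmax
    ranges = {
        k: community_fva(community, obj, FlowRef("biomass", species=k), 1.0,
                         options=options)
        for k in community.species_ids
    }
    return vmax, ranges


def solve_descriptive(
    community: CommunityModel,
    obj: OuterObjective | None = None,
    experimental: list[ConstraintSpec] | None = None,
    options: SolverOptions | None = None,
) -> CommunitySolution:
    """Infer optimality levels under experimental constraints.

    Stage 1 computes each species' community-specific maximum (predictive,
    without the experimental constraints). Stage 2 maximizes the outer
    objective over the single-level community polytope — inner optimality
    *not* enforced — with the experimental constraints added. Stage 3 reports
    c_k = v_bio_k / v_max_k (NaN when v_max_k = 0): < 1 sub-optimal,
    = 1 optimal, > 1 super-optimal growth at the expense of other members.
    """
    obj = obj or OuterObjective.total_biomass()
    options = options or SolverOptions()
    experimental = list(experimental or [])
    vmax = compute_species_maxima(community, obj, options=options)

    program = CommunityProgram(community, extra_constraints=tuple(experimental))
    c_outer = program.outer_objective_vector(obj)
    res = program.solve_relaxation(c_outer)
    if res.status == "infeasible":
        violated = program.diagnose_infeasibility()
        return CommunitySolution(
            status="infeasible", mode="descriptive", method="lp",
            v_max=vmax,
            meta={"message": "experimental constraints infeasible: " + ", ".join(violated),
                  "violated": violated},
        )
    if res.status == "unbounded":
        return CommunitySolution(status="unbounded", mode="descriptive", method="lp",
                                 v_max=vmax, meta={})
    opt = float(res.objective)
    x = res.x
    if options.tie_break:
        res2 = program.solve_relaxation(
            _flow_cost_vector(program, program.ncont), sense="min",
            extra_rows=(c_outer, opt - _OPT_EPS, math.inf),
        )
        if res2.optimal:
            x = res2.x
    sol = _extract(program, x, "descriptive", "lp", opt)
    sol.v_max = vmax
    sol.c = {
        k: (sol.biomass(k) / vmax[k] if vmax[k] > GAP_TOL else math.nan)
        for k in community.species_ids
    }
    sol.inner_gaps = _inner_gaps(program, sol)
    return sol


# ---------------------------------------------------------------------------
# community flux variability analysis
# ---------------------------------------------------------------------------
def community_fva(
    community: CommunityModel,
    obj: OuterObjective | None = None,
    target: FlowRef | str | tuple = None,
    fraction: float = 1.0,
    options: SolverOptions | None = None,
) -> tuple[float, float]:
    """Range of a flux, pool flow, or flow ratio at near-optimal community states.

    Minimizes and maximizes ``target`` subject to the outer objective staying
    >= ``fraction`` times its predictive optimum, with every species'
    inner-optimality certificate retained. A ratio target is a pair
    ``(numerator, denominator)`` of references and is resolved by bisection
    on the constraint num - r * den = 0 (the denominator must be bounded
    away from zero over the examined region).
    """
    obj = obj or OuterObjective.total_biomass()
    options = options or SolverOptions()
    base = solve_predictive(community, obj, options=options)
    if not base.optimal:
        raise InfeasibleError(f"predictive base solve is {base.status}")
    opt = base.objective
    program = CommunityProgram(community)
    kkt = program.kkt_extension(base.meta.get("big_m", options.big_m),
                                base.meta.get("big_m", options.big_m))
    c_outer = program.outer_objective_vector(obj, kkt.n_total)
    A, lo, hi = _append_row(kkt.A, kkt.row_lb, kkt.row_ub, c_outer,
                            fraction * opt - _OPT_EPS, math.inf)

    def _col_vec(ref: FlowRef | str) -> np.ndarray:
        r = parse_flow_ref(ref) if isinstance(ref, str) else ref
        c = np.zeros(kkt.n_total)
        for col, coef in program.ref_vector(r, net=True).items():
            c[col] = coef
        return c

    if isinstance(target, tuple):
        num, den = (_col_vec(t) for t in target)
        return _ratio_fva(A, lo, hi, kkt, num, den, options)
    c_t = _col_vec(target)
    out = []
    for sense in ("min", "max"):
        res = solve_milp(c_t, A, lo, hi, kkt.var_lb, kkt.var_ub,
                         kkt.integrality, sense=sense, time_limit=options.time_limit)
        if not res.optimal:
            raise InfeasibleError(f"community FVA subproblem status {res.status}")
        out.append(float(res.objective))
    return out[0], out[1]


def _ratio_fva(A, lo, hi, kkt, num: np.ndarray, den: np.ndarray,
               options: SolverOptions, tol: float = 1e-6) -> tuple[float, float]:
    def extreme(vec, sense):
        res = solve_milp(vec, A, lo, hi, kkt.var_lb, kkt.var_ub, kkt.integrality,
                         sense=sense, time_limit=options.time_limit)
        if not res.optimal:
            raise InfeasibleError(f"ratio FVA bound solve status {res.status}")
        return float(res.objective)

    den_min, den_max = extreme(den, "min"), extreme(den, "max")
    if den_min <= tol:
        raise ConfigurationError(
            "ratio FVA requires the denominator flow to stay positive over the region"
        )
    num_min, num_max = extreme(num, "min"), extreme(num, "max")

    def feasible(r: float) -> bool:
        A2, lo2, hi2 = _append_row(A, lo, hi, num - r * den, 0.0, 0.0)
        res = solve_milp(np.zeros(kkt.n_total), A2, lo2, hi2, kkt.var_lb,
                         kkt.var_ub, kkt.integrality, sense="min",
                         time_limit=options.time_limit)
        return res.optimal

    r_lo_init = max(num_min / den_max, 0.0) if num_min >= 0 else num_min / den_min
    r_hi_init = num_max / den_min if num_max >= 0 else num_max / den_max
    # find one feasible anchor by scanning the candidate interval
    anchors = np.linspace(r_lo_init, r_hi_init, 9)
    r0 = next((r for r in anchors if feasible(r)), None)
    if r0 is None:
        raise InfeasibleError("no feasible ratio found in the candidate interval")

    def bisect(direction: str) -> float:
        good = r0
        bad = r_hi_init if direction == "up" else r_lo_init
        if feasible(bad):
            return bad
        for _ in range(60):
            mid = 0.5 * (good + bad)
            if feasible(mid):
                good = mid
            else:
                bad = mid
            if abs(bad - good) <= tol * max(1.0, abs(good)):
                break
        return good

    return bisect("down"), bisect("up")


# ---------------------------------------------------------------------------
# scenario batches
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Scenario:
    name: str
    constraints: tuple[ConstraintSpec, ...] = ()
    medium: dict[str, float] | None = None
    mode: str = "predictive"
    obj: OuterObjective | None = None
    method: str = "dual_milp"


def run_scenarios(
    community: CommunityModel,
    scenarios: list[Scenario],
    options: SolverOptions | None = None,
) -> list[CommunitySolution]:
    """Independent per-scenario solves (one per experimental interval).

    Order-preserving; a failing scenario is recorded with status ``error``
    (or ``infeasible``) without aborting the batch.
    """
    out: list[CommunitySolution] = []
    for sc in scenarios:
        try:
            com = community
            if sc.medium:
                med = dict(com.medium)
                med.update(sc.medium)
                com = replace(com, medium=med, constraints=list(com.constraints))
            if sc.mode == "predictive":
                for spec in sc.constraints:
                    com = add_constraint(com, spec)
                sol = solve_predictive(com, sc.obj, method=sc.method, options=options)
            elif sc.mode == "descriptive":
                sol = solve_descriptive(com, sc.obj, list(sc.constraints), options=options)
            else:
                raise ConfigurationError(f"scenario '{sc.name}': unknown mode '{sc.mode}'")
            sol.meta["scenario"] = sc.name
            out.append(sol)
        except Exception as exc:
            log.warning("scenario '%s' failed: %s", sc.name, exc)
            out.append(CommunitySolution(
                status="error", mode=sc.mode, method=sc.method,
                meta={"scenario": sc.name, "message": str(exc)},
            ))
    return out
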