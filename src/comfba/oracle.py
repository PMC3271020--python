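"""Brute-force verification of the multilevel solvers.

The grid oracle enumerates inter-organism flow allocations on a regular
grid, solves every species' inner biomass LP at each allocation, and keeps
the best community objective. It is deliberately independent of the KKT /
strong-duality machinery: a finite-resolution lower bound on the true
predictive optimum, used to cross-check the exact solvers on desk-scale
communities (its intended scale is <= ~3 species and ~2 shared metabolites;
it is a test instrument, not a production solver).

Enumeration runs over *net* flows (export - uptake), one dimension per
(species, coupling metabolite) pair minus one species eliminated per pool
balance, plus one dimension for the environment when the pool has external
supply or may accumulate. Shared metabolites touched by a single species do
not couple anything and are relaxed to interval bounds inside that species'
inner LP — equivalent for the optimum, exponentially cheaper. Grids are
anchored at zero (multiples of the resolution clipped to the feasible
range), so the zero allocation is always examined when admissible.

:func:`certify` independently re-solves each inner LP at a returned
solution's allocation and reports the per-species optimality gap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from ._evaluate import InnerSolver, evaluate_allocation
from ._program import CommunityProgram
from .community import CommunityModel
from .errors import ConfigurationError
from .multilevel import CommunitySolution, OuterObjective

__all__ = ["OracleResult", "grid_oracle", "certify"]

_BALANCE_EPS = 1e-9


@dataclass
class OracleResult:
    #: (species, shared-met) -> (uptake, export) at the best allocation
    best_allocation: dict[tuple[str, str], tuple[float, float]] | None
    best_objective: float | None
    grid_resolution: float
    evaluations: int
    #: biomass of each species at the best allocation
    best_biomass: dict[str, float] | None = None


def _grid(lo: float, hi: float, res: float) -> np.ndarray:
    """Zero-anchored grid: multiples of ``res`` inside [lo, hi]."""
    k0 = math.ceil(lo / res - 1e-9)
    k1 = math.floor(hi / res + 1e-9)
    if k1 < k0:
        return np.array([min(max(0.0, lo), hi)])
    return np.arange(k0, k1 + 1) * res


def grid_oracle(
    c: CommunityModel,
    obj: OuterObjective | None = None,
    resolution: float = 1.0,
    max_evaluations: int = 1_000_000,
) -> OracleResult:
    """Exhaustive grid search over inter-organism flow allocations.

    Every admissible allocation on the grid is evaluated by fixing the
    coupled net flows, solving each species' inner LP to optimality
    (optimistic about alternate inner optima), discarding allocations that
    violate pool balances or flow direction bounds, and scoring the outer
    objective on the inner-optimal responses.

    Requires every enumerated flow dimension to have a finite range (taken
    from the single-level relaxation); raises otherwise.
    """
    obj = obj or OuterObjective.total_biomass()
    if resolution <= 0:
        raise ConfigurationError("resolution must be positive")
    program = CommunityProgram(c)
    outer_vec = program.outer_objective_vector(obj)
    inner = {k: InnerSolver(program, k) for k in c.species_ids}
    acc = c.effective_accumulation()

    coupling = [i for i in c.shared_ids if len(c.touchers(i)) >= 2]
    ranges: dict[tuple[str, str], tuple[float, float]] = {}
    for i in coupling:
        for k in c.touchers(i):
            lo, hi = program.net_flow_range(k, i)
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ConfigurationError(
                    f"net flow of '{i}' for species '{k}' is unbounded; "
                    "a finite grid needs finite shared-flow bounds"
                )
            ranges[(k, i)] = (lo, hi)

    # enumerated axes: all but the last toucher per coupling metabolite,
    # plus the environment exchange d = u_c - e_c where it can be nonzero
    axes: list[tuple[str, ...]] = []
    grids: list[np.ndarray] = []
    eliminated: dict[str, str] = {}
    for i in coupling:
        touchers = c.touchers(i)
        eliminated[i] = touchers[-1]
        for k in touchers[:-1]:
            axes.append(("net", k, i))
            grids.append(_grid(*ranges[(k, i)], resolution))
        med_i, acc_i = c.medium.get(i, 0.0), acc.get(i, 0.0)
        if med_i > 0 or acc_i > 0:
            if not (math.isfinite(med_i) and math.isfinite(acc_i)):
                raise ConfigurationError(
                    f"environment exchange of '{i}' is unbounded; cannot grid"
                )
            axes.append(("env", "", i))
            grids.append(_grid(-acc_i, med_i, resolution))

    # non-coupling metabolites: relaxed to interval row bounds
    relaxed: dict[str, dict[str, tuple[float, float]]] = {k: {} for k in c.species_ids}
    for i in c.shared_ids:
        if i in coupling:
            continue
        for k in c.touchers(i):
            med_i, acc_i = c.medium.get(i, 0.0), acc.get(i, 0.0)
            relaxed[k][i] = (-med_i, acc_i)

    n_eval = int(np.prod([g.size for g in grids])) if grids else 1
    if n_eval > max_evaluations:
        raise ConfigurationError(
            f"grid would need {n_eval} evaluations (> {max_evaluations}); "
            "coarsen the resolution"
        )

    best: tuple[float, np.ndarray, dict[str, float]] | None = None
    for combo in itertools.product(*grids) if grids else [()]:
        nets: dict[tuple[str, str], float] = {}
        env: dict[str, float] = {}
        ok = True
        for (kind, k, i), val in zip(axes, combo):
            if kind == "net":
                nets[(k, i)] = float(val)
            else:
                env[i] = float(val)
        for i in coupling:
            d = env.get(i, 0.0)
            others = sum(nets[(k, i)] for k in c.touchers(i)[:-1])
            last = -others - d  # pool balance, exact by elimination
            lo, hi = ranges[(eliminated[i], i)]
            if last < lo - _BALANCE_EPS or last > hi + _BALANCE_EPS:
                ok = False
                break
            nets[(eliminated[i], i)] = last
        if not ok:
            continue
        net_bounds = {
            k: dict(relaxed[k]) | {
                i: (nets[(k, i)], nets[(k, i)])
                for i in coupling if (k, i) in nets
            }
            for k in c.species_ids
        }
        result = evaluate_allocation(program, inner, net_bounds, outer_vec)
        if result is None:
            continue
        val, x, _ = result
        if best is None or val > best[0] + 1e-12:
            bio = {k: float(x[program.v_col[(k, c.species_by_id(k).biomass_id)]])
                   for k in c.species_ids}
            best = (val, x, bio)

    if best is None:
        return OracleResult(None, None, resolution, n_eval)
    val, x, bio = best
    allocation = {
        (k, i): (float(x[program.u_col[(k, i)]]), float(x[program.e_col[(k, i)]]))
        for (k, i) in c.flow_pairs()
    }
    return OracleResult(allocation, float(val), resolution, n_eval, bio)


def certify(sol: CommunitySolution, c: CommunityModel) -> dict[str, float]:
    """Independent optimality certification of a community solution.

    Re-solves each species' inner LP with the pool flows fixed at the
    solution's allocation and returns z_k - v_bio_k per species (infinity if
    the allocation is infeasible for the species). Predictive solutions must
    certify to <= 1e-6.
    """
    program = CommunityProgram(c)
    gaps: dict[str, float] = {}
    for k in c.species_ids:
        solver = InnerSolver(program, k)
        nets = {}
        for i in sol.uptake.get(k, {}):
            net = sol.export[k][i] - sol.uptake[k][i]
            band = 1e-8 * max(1.0, abs(net))  # absorb solver round-off
            nets[i] = (net - band, net + band)
        z = solver.optimum(nets)
        gaps[k] = math.inf if z is None else z - sol.biomass(k)
    return gaps
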