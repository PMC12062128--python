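"""Linear-programming engine for constraint-based flux analysis.

Implements flux balance analysis (FBA), parsimonious FBA (pFBA), flux
variability analysis (FVA), seeded hit-and-run sampling of the
near-optimal flux polytope, and the uptake-normalised flux reporting
used throughout the analysis.  All linear programs are solved with the
HiGHS backend of :func:`scipy.optimize.linprog`.

Conventions
-----------
Flux units are mmol/gCDW/h (the biomass reaction is scaled so its flux
is the specific growth rate in 1/h).  On exchange reactions, uptake is
negative and secretion positive.  Measured rates are imposed as
two-sided ("fixed") constraints: lower bound = upper bound = value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model_core import StoichiometricModel

__all__ = [
    "FluxConstraintSet",
    "FluxSolution",
    "SamplingSummary",
    "InfeasibleProblemError",
    "apply_measured_rates",
    "solve_fba",
    "solve_pfba",
    "flux_variability",
    "sample_solution_space",
    "normalize_by_uptake",
    "route_fraction",
    "write_flux_table",
    "read_rate_table",
]

SOLVER_TOL = 1e-9       # LP solver tolerance
FEASIBILITY_TOL = 1e-6  # tolerance for S.v = 0 / bound assertions


class InfeasibleProblemError(RuntimeError):
    """Raised when an operation requires a feasible LP but got none."""


@dataclass
class FluxConstraintSet:
    """Per-reaction flux bounds overriding the model defaults.

    ``bounds`` maps reaction id -> (lower, upper); ``provenance`` tags
    each entry as ``measured`` or ``default``.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def resolved(self, model: StoichiometricModel) -> dict[str, tuple[float, float]]:
        """Full bound map: model defaults overridden by this set."""
        out = {rid: (r.lower_bound, r.upper_bound)
               for rid, r in model.reactions.items()}
        for rid, (lb, ub) in self.bounds.items():
            if rid not in out:
                raise KeyError(f"unknown reaction id {rid!r} in constraint set")
            if lb > ub:
                raise ValueError(f"constraint on {rid!r}: lower > upper")
            out[rid] = (lb, ub)
        return out


@dataclass
class FluxSolution:
    """Outcome of one LP: solver status, objective and the flux vector."""

    status: str                       # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class SamplingSummary:
    """Per-reaction flux statistics over sampled points."""

    n_samples: int
    seed: int
    growth_fraction: float
    stats: dict[str, tuple[float, float, float, float]]  # median, sd, min, max
    #: raw sample matrix (n_samples x reactions), kept only on request
    points: "np.ndarray | None" = field(default=None, compare=False, repr=False)
    reaction_ids: list[str] | None = field(default=None, compare=False, repr=False)

    def median(self, rxn_id: str) -> float:
        return self.stats[rxn_id][0]

    def as_flux_map(self) -> dict[str, float]:
        return {rid: s[0] for rid, s in self.stats.items()}


def apply_measured_rates(model: StoichiometricModel,
                         rates: Mapping[str, float],
                         base: FluxConstraintSet | None = None,
                         ) -> FluxConstraintSet:
    """Fix measured specific rates as two-sided flux constraints.

    Each entry pins the named exchange/transport reaction to the
    measured value by setting lower = upper = value (uptake negative on
    exchanges).  All other bounds are inherited from ``base`` or the
    model defaults.
    """
    cs = FluxConstraintSet(dict(base.bounds) if base else {},
                           dict(base.provenance) if base else {})
    for rid, value in rates.items():
        if rid not in model.reactions:
            raise KeyError(f"unknown reaction id {rid!r}")
        cs.bounds[rid] = (float(value), float(value))
        cs.provenance[rid] = "measured"
    return cs


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def _lp_arrays(model: StoichiometricModel,
               constraints: FluxConstraintSet | None):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    bmap = (constraints or FluxConstraintSet()).resolved(model)
    bounds = np.array([bmap[rid] for rid in rxn_ids], dtype=float)
    return S, rxn_ids, bounds


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded",
           4: "numerical difficulty"}


def _solve(S: np.ndarray, bounds: np.ndarray, c: np.ndarray,
           extra_A_ub: np.ndarray | None = None,
           extra_b_ub: np.ndarray | None = None):
    res = linprog(c, A_ub=extra_A_ub, b_ub=extra_b_ub,
                  A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs",
                  options={"primal_feasibility_tolerance": SOLVER_TOL,
                           "dual_feasibility_tolerance": SOLVER_TOL})
    status = _STATUS.get(res.status, "failed")
    if status == "iteration limit" or status == "numerical difficulty":
        status = "failed"
    return res, status


def solve_fba(model: StoichiometricModel,
              constraints: FluxConstraintSet | None = None,
              objective_id: str | None = None,
              direction: str = "max") -> FluxSolution:
    """Solve max/min c.v subject to S.v = 0 and flux bounds."""
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    objective_id = objective_id or model.objective_id
    S, rxn_ids, bounds = _lp_arrays(model, constraints)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = -1.0 if direction == "max" else 1.0
    res, status = _solve(S, bounds, c)
    if status != "optimal":
        return FluxSolution(status, float("nan"), {})
    obj = float(res.x[rxn_ids.index(objective_id)])
    return FluxSolution("optimal", obj, dict(zip(rxn_ids, map(float, res.x))))


def solve_pfba(model: StoichiometricModel,
               constraints: FluxConstraintSet | None = None,
               objective_id: str | None = None) -> FluxSolution:
    """Parsimonious FBA: maximise growth, then minimise total |flux|.

    Stage 1 maximises the objective; stage 2 fixes the objective at the
    stage-1 optimum (within 1e-9 relative) and minimises the sum of
    absolute fluxes via an irreversible split v = v+ - v- with
    v+, v- >= 0.  The split is internal; the returned solution is in the
    original reaction space and its objective equals the stage-1 optimum
    within tolerance.
    """
    objective_id = objective_id or model.objective_id
    stage1 = solve_fba(model, constraints, objective_id, "max")
    if not stage1.ok:
        return stage1
    opt = stage1.objective_value

    S, rxn_ids, bounds = _lp_arrays(model, constraints)
    iobj = rxn_ids.index(objective_id)
    slack = max(1e-9 * abs(opt), 1e-12)
    bounds = bounds.copy()
    bounds[iobj, 0] = max(bounds[iobj, 0], opt - slack)
    bounds[iobj, 1] = min(bounds[iobj, 1], opt + slack)

    n = len(rxn_ids)
    # split: x = [v+, v-], v = v+ - v-
    S2 = np.hstack([S, -S])
    lb, ub = bounds[:, 0], bounds[:, 1]
    split_bounds = np.zeros((2 * n, 2))
    split_bounds[:n, 1] = np.maximum(ub, 0.0)
    split_bounds[n:, 1] = np.maximum(-lb, 0.0)
    split_bounds[:n, 0] = np.maximum(lb, 0.0)
    split_bounds[n:, 0] = np.maximum(-ub, 0.0)
    c = np.ones(2 * n)
    res, status = _solve(S2, split_bounds, c)
    if status != "optimal":
        return FluxSolution(status, float("nan"), {})
    v = res.x[:n] - res.x[n:]
    return FluxSolution("optimal", float(v[iobj]),
                        dict(zip(rxn_ids, map(float, v))))


def _growth_floor_arrays(model, constraints, growth_fraction, objective_id):
    """Bounds with the objective lower bound raised to fraction*optimum."""
    opt_sol = solve_fba(model, constraints, objective_id, "max")
    if not opt_sol.ok:
        raise InfeasibleProblemError(
            f"FBA is {opt_sol.status}; cannot constrain near-optimal growth")
    S, rxn_ids, bounds = _lp_arrays(model, constraints)
    iobj = rxn_ids.index(objective_id)
    floor = growth_fraction * opt_sol.objective_value
    bounds = bounds.copy()
    # tiny backoff keeps the floored polytope numerically full-dimensional
    bounds[iobj, 0] = max(bounds[iobj, 0], floor - 1e-9 * max(1.0, abs(floor)))
    return S, rxn_ids, bounds, opt_sol


def flux_variability(model: StoichiometricModel,
                     constraints: FluxConstraintSet | None = None,
                     growth_fraction: float = 0.9,
                     objective_id: str | None = None,
                     reactions: Sequence[str] | None = None,
                     ) -> dict[str, tuple[float, float]]:
    """Per-reaction flux (min, max) at growth >= fraction * optimum."""
    objective_id = objective_id or model.objective_id
    S, rxn_ids, bounds, _ = _growth_floor_arrays(
        model, constraints, growth_fraction, objective_id)
    targets = list(reactions) if reactions is not None else rxn_ids
    out: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        c = np.zeros(len(rxn_ids))
        lohi = []
        for sign in (1.0, -1.0):
            c[j] = sign
            res, status = _solve(S, bounds, c)
            if status != "optimal":
                raise InfeasibleProblemError(
                    f"FVA subproblem for {rid!r} is {status}")
            lohi.append(sign * res.fun)
        out[rid] = (float(lohi[0]), float(lohi[1]))
    return out


def sample_solution_space(model: StoichiometricModel,
                          constraints: FluxConstraintSet | None = None,
                          n: int = 2000,
                          growth_fraction: float = 0.9,
                          seed: int | None = None,
                          objective_id: str | None = None,
                          thinning: int = 10,
                          return_points: bool = False,
                          ) -> SamplingSummary:
    """Seeded hit-and-run sampling of the near-optimal flux polytope.

    The growth floor (``growth_fraction`` times the FBA optimum) is
    imposed as a bound on the objective reaction; the walk then moves
    inside the null space of S (so every point satisfies S.v = 0 by
    construction), one null-space coordinate direction per step, keeping
    every ``thinning``-th point.  The chain is warm-started from the
    average of the FVA-extreme solutions, a feasible interior point by
    convexity.  Returns per-reaction median, sd, min and max.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if seed is None:
        raise ValueError("sampling requires an explicit seed")
    rng = np.random.default_rng(seed)
    objective_id = objective_id or model.objective_id
    S, rxn_ids, bounds, _ = _growth_floor_arrays(
        model, constraints, growth_fraction, objective_id)
    nrxn = len(rxn_ids)

    # warm start: mean of FVA vertex solutions (feasible by convexity)
    pts = []
    c = np.zeros(nrxn)
    for j in range(nrxn):
        if bounds[j, 0] == bounds[j, 1]:
            continue
        for sign in (1.0, -1.0):
            c[:] = 0.0
            c[j] = sign
            res, status = _solve(S, bounds, c)
            if status != "optimal":
                raise InfeasibleProblemError(
                    f"sampling warm-start subproblem is {status}")
            pts.append(res.x)
    if not pts:  # fully fixed polytope: a single point
        res, status = _solve(S, bounds, np.zeros(nrxn))
        if status != "optimal":
            raise InfeasibleProblemError(f"polytope is {status}")
        pts.append(res.x)
    x = np.mean(pts, axis=0)

    # null-space basis of S: directions that keep S.v = 0
    from scipy.linalg import null_space
    N = null_space(S)
    lb, ub = bounds[:, 0], bounds[:, 1]
    x = np.clip(x, lb, ub)

    samples = np.empty((n, nrxn))
    ndir = N.shape[1]
    eps = 1e-12
    for k in range(n * thinning):
        d = N[:, rng.integers(ndir)]
        # admissible step interval from the box bounds
        with np.errstate(divide="ignore", invalid="ignore"):
            lo_steps = (lb - x) / d
            hi_steps = (ub - x) / d
        tmin, tmax = -np.inf, np.inf
        mask = np.abs(d) > 1e-10
        lo = np.where(d > 0, lo_steps, hi_steps)[mask]
        hi = np.where(d > 0, hi_steps, lo_steps)[mask]
        if lo.size:
            tmin = np.max(lo)
            tmax = np.min(hi)
        if np.isfinite(tmin) and np.isfinite(tmax) and tmax - tmin >= eps:
            x = x + d * rng.uniform(tmin, tmax)
            x = np.clip(x, lb, ub)
        if (k + 1) % thinning == 0:
            samples[(k + 1) // thinning - 1] = x
    stats = {}
    for j, rid in enumerate(rxn_ids):
        col = samples[:, j]
        stats[rid] = (float(np.median(col)), float(np.std(col, ddof=1)),
                      float(col.min()), float(col.max()))
    return SamplingSummary(n, seed, growth_fraction, stats,
                           points=samples if return_points else None,
                           reaction_ids=list(rxn_ids) if return_points else None)


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def normalize_by_uptake(fluxes: Mapping[str, float] | FluxSolution | SamplingSummary,
                        uptake_id: str) -> dict[str, float]:
    """Divide every flux by the absolute substrate uptake rate."""
    if isinstance(fluxes, FluxSolution):
        fmap = fluxes.fluxes
    elif isinstance(fluxes, SamplingSummary):
        fmap = fluxes.as_flux_map()
    else:
        fmap = dict(fluxes)
    denom = abs(fmap[uptake_id])
    if denom <= 1e-9:
        raise ZeroDivisionError(
            f"uptake flux of {uptake_id!r} is zero; cannot normalize")
    return {rid: v / denom for rid, v in fmap.items()}


def route_fraction(fluxes: Mapping[str, float] | FluxSolution,
                   numerator_ids: Iterable[str],
                   denominator_ids: Iterable[str]) -> float:
    """Fraction of total flux magnitude carried by a subset of routes."""
    fmap = fluxes.fluxes if isinstance(fluxes, FluxSolution) else fluxes
    num = sum(abs(fmap[rid]) for rid in numerator_ids)
    den = sum(abs(fmap[rid]) for rid in denominator_ids)
    if den <= 0:
        raise ZeroDivisionError("route denominator flux is zero")
    return num / den


def write_flux_table(path: str | Path,
                     solution: FluxSolution | None = None,
                     summary: SamplingSummary | None = None,
                     normalized: Mapping[str, float] | None = None) -> Path:
    """Write a TSV flux report (reaction, flux, normalized, sampling stats)."""
    path = Path(path)
    ids: list[str] = []
    if solution is not None:
        ids = list(solution.fluxes)
    elif summary is not None:
        ids = list(summary.stats)
    header = ["reaction", "flux", "normalized_flux", "median", "sd", "min", "max"]
    rows = []
    for rid in ids:
        flux = f"{solution.fluxes[rid]:.10g}" if solution else ""
        norm = f"{normalized[rid]:.10g}" if normalized and rid in normalized else ""
        if summary and rid in summary.stats:
            med, sd, lo, hi = summary.stats[rid]
            stat_cols = [f"{med:.10g}", f"{sd:.10g}", f"{lo:.10g}", f"{hi:.10g}"]
        else:
            stat_cols = ["", "", "", ""]
        rows.append("\t".join([rid, flux, norm, *stat_cols]))
    path.write_text("\n".join(["\t".join(header), *rows]) + "\n")
    return path


def read_rate_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (reaction id, measured rate)."""
    rates: dict[str, float] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {i + 1}: expected 'id<TAB>value'")
        if i == 0 and parts[0].lower() in ("reaction", "id", "reaction_id"):
            continue
        rates[parts[0]] = float(parts[1])
    return rates
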