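"""Per-step linear programs: FBA, minimisation of total flux, FVA.

All three solve over the steady-state polytope {v : S v = 0, lb <= v <= ub}.
The backend is SciPy's HiGHS solver behind this module's surface; alternate
LP backends can return different optimal vertices for degenerate problems,
which is why the engine offers MTF as a tie-breaking second stage.

Numerical constants: feasibility checks use ``FEASIBILITY_TOL`` (1e-9),
optimality comparisons ``OPTIMALITY_TOL`` (1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .exceptions import ModelValidationError
from .model_io import MetabolicModel

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-6

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"

BoundsMap = dict[str, tuple[float, float]]


@dataclass
class FluxSolution:
    """One LP solution: flux vector, objective value and solver status."""

    fluxes: pd.Series            # mmol/gDW/h per reaction; empty if not optimal
    objective_value: float       # c . v (NaN if not optimal)
    status: str                  # optimal | infeasible | unbounded
    method: str = "FBA"

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class FVAResult:
    """Per-reaction flux ranges at objective fraction ``objective_fraction``."""

    min_flux: pd.Series
    max_flux: pd.Series
    objective_fraction: float
    status: str = OPTIMAL


def _problem_arrays(
    model: MetabolicModel, bounds: BoundsMap | None
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]], list[str]]:
    S = model.stoichiometric_matrix().to_numpy()
    rids = model.reaction_ids
    c = np.array([r.objective_coefficient for r in model.reactions], dtype=float)
    lp_bounds = []
    for rxn in model.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if bounds is not None and rxn.id in bounds:
            lb, ub = bounds[rxn.id]
        if lb > ub:
            raise ModelValidationError(
                f"reaction {rxn.id!r}: effective lower bound {lb} > upper bound {ub}"
            )
        lp_bounds.append((lb, ub))
    return S, c, lp_bounds, rids


def _run_linprog(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    if res.status not in _STATUS:
        raise RuntimeError(f"HiGHS backend failure: {res.message}")
    return res


def solve_fba(model: MetabolicModel, bounds: BoundsMap | None = None) -> FluxSolution:
    """Maximise the objective flux over the steady-state polytope.

    ``bounds`` overrides per-reaction (lb, ub) without mutating the model —
    this is how the dynamic engine imposes its per-step constraints.
    Infeasibility is returned as data (``status="infeasible"``), not raised.
    """
    S, c, lp_bounds, rids = _problem_arrays(model, bounds)
    if not np.any(c):
        raise ModelValidationError(
            f"model {model.id!r} has an all-zero objective; FBA is undefined"
        )
    res = _run_linprog(-c, S, np.zeros(S.shape[0]), lp_bounds)
    status = _STATUS[res.status]
    if status != OPTIMAL:
        return FluxSolution(pd.Series(dtype=float), float("nan"), status, "FBA")
    fluxes = pd.Series(res.x, index=rids)
    return FluxSolution(fluxes, float(c @ res.x), OPTIMAL, "FBA")


def solve_mtf(
    model: MetabolicModel,
    objective_fraction: float = 1.0,
    bounds: BoundsMap | None = None,
) -> FluxSolution:
    """Minimise total absolute flux while holding the FBA objective.

    Two-stage parsimonious construction: first FBA gives Z*, then each flux
    is split into non-negative forward/reverse parts and sum(f + r) is
    minimised subject to S v = 0, the original bounds and
    c . v >= objective_fraction * Z*.
    """
    if not (0.0 < objective_fraction <= 1.0):
        raise ModelValidationError(
            f"objective_fraction must be in (0, 1], got {objective_fraction}"
        )
    fba = solve_fba(model, bounds)
    if not fba.optimal:
        return FluxSolution(pd.Series(dtype=float), float("nan"), fba.status, "MTF")
    S, c, lp_bounds, rids = _problem_arrays(model, bounds)
    n = len(rids)
    # v = f - r with f in [max(lb,0), max(ub,0)], r in [max(-ub,0), max(-lb,0)]
    split_bounds = []
    for lb, ub in lp_bounds:
        split_bounds.append((max(lb, 0.0), max(ub, 0.0)))
    for lb, ub in lp_bounds:
        split_bounds.append((max(-ub, 0.0), max(-lb, 0.0)))
    S2 = np.hstack([S, -S])
    c2 = np.concatenate([c, -c])
    z_target = objective_fraction * fba.objective_value
    res = _run_linprog(
        np.ones(2 * n), S2, np.zeros(S.shape[0]), split_bounds,
        A_ub=-c2[None, :], b_ub=np.array([-z_target]),
    )
    status = _STATUS[res.status]
    if status != OPTIMAL:
        return FluxSolution(pd.Series(dtype=float), float("nan"), status, "MTF")
    v = res.x[:n] - res.x[n:]
    fluxes = pd.Series(v, index=rids)
    return FluxSolution(fluxes, float(c @ v), OPTIMAL, "MTF")


def solve_fva(
    model: MetabolicModel,
    objective_fraction: float = 1.0,
    bounds: BoundsMap | None = None,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Per-reaction flux min/max at a fraction of the FBA optimum."""
    if not (0.0 <= objective_fraction <= 1.0):
        raise ModelValidationError(
            f"objective_fraction must be in [0, 1], got {objective_fraction}"
        )
    fba = solve_fba(model, bounds)
    if not fba.optimal:
        empty = pd.Series(dtype=float)
        return FVAResult(empty, empty, objective_fraction, status=fba.status)
    S, c, lp_bounds, rids = _problem_arrays(model, bounds)
    targets = reactions if reactions is not None else rids
    z_target = objective_fraction * fba.objective_value
    A_ub = -c[None, :]
    b_ub = np.array([-z_target + OPTIMALITY_TOL])
    mins, maxs = {}, {}
    zeros = np.zeros(S.shape[0])
    for rid in targets:
        i = rids.index(rid)
        obj = np.zeros(len(rids))
        obj[i] = 1.0
        lo = _run_linprog(obj, S, zeros, lp_bounds, A_ub=A_ub, b_ub=b_ub)
        hi = _run_linprog(-obj, S, zeros, lp_bounds, A_ub=A_ub, b_ub=b_ub)
        if _STATUS[lo.status] != OPTIMAL or _STATUS[hi.status] != OPTIMAL:
            empty = pd.Series(dtype=float)
            return FVAResult(empty, empty, objective_fraction, status=INFEASIBLE)
        mins[rid] = float(lo.x[i])
        maxs[rid] = float(hi.x[i])
    return FVAResult(pd.Series(mins), pd.Series(maxs), objective_fraction)


def total_flux(solution: FluxSolution) -> float:
    """sum |v_i| of a flux solution (the MTF objective)."""
    return float(np.abs(solution.fluxes.to_numpy()).sum())
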