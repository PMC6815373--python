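"""Adaptive DFBA engine (static optimisation approach).

The simulation advances on a fixed grid t = 0, dt, 2*dt, ... At every step
it (1) applies user interventions — scheduled or feedback-driven changes to
reaction bounds and to medium concentrations, (2) tightens uptake lower
bounds so no more substrate can be consumed in one step than the medium
holds, (3) solves the step's LP (FBA, optionally followed by total-flux
minimisation, optionally bracketed by FVA), and (4) integrates biomass and
concentrations forward.

Biomass is decoupled from the LP objective: growth is always read from the
flux of the *biomass reaction*, so the objective may be secretion or any
other flux, conflicting with growth or not.

Substrate conventions (medium concentrations, mmol/L):

* zero marks an absent substrate (uptake clamped to 0 until it is produced);
* a negative initial value marks a substrate in unlimited EXCESS — it is
  never clamped and its concentration is not tracked (cumulative exchange is
  accumulated separately);
* exchanged metabolites not mentioned at all default to EXCESS, with a
  logged warning.

An infeasible LP ends the run early; that is a simulation *result* (the
partial trajectory is returned with a termination reason), not an error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    ContractError,
    IntegrationError,
    ScheduleError,
)
from .lp_core import BoundsMap, FluxSolution, solve_fba, solve_fva, solve_mtf
from .model_io import (
    EXCESS,
    MetabolicModel,
    Trajectory,
    exchanged_metabolite,
    find_biomass_reaction,
    identify_exchange_reactions,
)

logger = logging.getLogger("adfba.dynamics")

#: Tolerance below which a concentration is treated as exactly exhausted.
CONC_TOL = 1e-9
#: Growth rates below this magnitude use the linear (Euler) update.
MU_TOL = 1e-9
#: Schedule times are matched to grid times within this tolerance (h).
TIME_MATCH_TOL = 1e-9

BoundsCallback = Callable[
    [MetabolicModel, dict[str, float], FluxSolution | None, float],
    Mapping[str, tuple[float, float]],
]
ConcentrationCallback = Callable[[dict[str, float]], Mapping[str, float]]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class InterventionSet:
    """Mid-run modifications, applied in a fixed order at each step:

    bounds schedule row -> bounds callback -> concentration schedule row
    (differential: zero means no change) -> concentration callback
    (replacement).  Callbacks run last so feedback logic sees the scheduled
    changes already applied.
    """

    bounds_schedule: pd.DataFrame | None = None
    bounds_callback: BoundsCallback | None = None
    concentration_schedule: pd.DataFrame | None = None
    concentration_callback: ConcentrationCallback | None = None

    def is_empty(self) -> bool:
        return (
            self.bounds_schedule is None
            and self.bounds_callback is None
            and self.concentration_schedule is None
            and self.concentration_callback is None
        )


@dataclass
class SimulationState:
    """Mutable per-step state of a run."""

    time: float                                  # h
    biomass: float                               # gDW/L
    concentrations: dict[str, float]             # mmol/L, tracked only
    excess: set[str]                             # metabolites in EXCESS
    current_bounds: BoundsMap                    # intervention-level bounds
    original_bounds: Mapping[str, tuple[float, float]]
    last_fluxes: FluxSolution | None = None
    excess_exchanged: dict[str, float] = field(default_factory=dict)  # mmol/L cumulative

    def snapshot_concentrations(self, order: list[str]) -> list[float]:
        return [
            float("nan") if m in self.excess else self.concentrations[m]
            for m in order
        ]


@dataclass
class RunContext:
    """Validated inputs: the immutable frame a run iterates inside."""

    model: MetabolicModel
    biomass_reaction: str
    biomass_warned: bool
    exchange_of: dict[str, str]       # metabolite -> exchange reaction id
    tracked: list[str]                # tracked metabolite order (stable)
    state: SimulationState
    interventions: InterventionSet


# ---------------------------------------------------------------------------
# Validation / pre-processing
# ---------------------------------------------------------------------------

def _parse_bound_column(name: str) -> tuple[str, str]:
    for tag in ("[low]", "[upp]"):
        if name.endswith(tag):
            return name[: -len(tag)], tag[1:-1]
    raise ScheduleError(
        f"bounds schedule column {name!r} must end in '[low]' or '[upp]'"
    )


def validate_setup(
    model: MetabolicModel,
    initial_concentrations: Mapping[str, float],
    initial_biomass: float,
    interventions: InterventionSet | None = None,
    *,
    dt: float = 1.0,
    biomass_reaction: str | None = None,
) -> RunContext:
    """Type-check and normalise all run inputs; build the initial state.

    Substrates may be listed in any order and as any subset of the exchanged
    metabolites.  Returns a :class:`RunContext` with the original bounds
    snapshotted so interventions can always be related back to them.
    """
    if not (initial_biomass > 0):
        raise ConfigurationError(
            f"initial biomass must be positive, got {initial_biomass}"
        )
    if not (dt > 0):
        raise ConfigurationError(f"time step dt must be positive, got {dt}")
    interventions = interventions or InterventionSet()

    biomass_id, warned = find_biomass_reaction(model, biomass_reaction)
    exchange_of: dict[str, str] = {}
    for rid in sorted(identify_exchange_reactions(model)):
        if rid == biomass_id:
            continue
        met = exchanged_metabolite(model, rid)
        if met in exchange_of:
            raise ConfigurationError(
                f"metabolite {met!r} has multiple exchange reactions "
                f"({exchange_of[met]!r}, {rid!r}); cannot track its concentration"
            )
        exchange_of[met] = rid

    unknown = set(initial_concentrations) - set(exchange_of)
    if unknown:
        raise ConfigurationError(
            f"initial concentrations name non-exchanged metabolites: {sorted(unknown)}"
        )

    concentrations: dict[str, float] = {}
    excess: set[str] = set()
    for met in exchange_of:
        if met not in initial_concentrations:
            logger.warning(
                "exchanged metabolite %s has no initial concentration; "
                "assuming EXCESS (unlimited)", met,
            )
            excess.add(met)
            continue
        x0 = float(initial_concentrations[met])
        if x0 < 0:
            excess.add(met)  # negative concentration marks unlimited excess
        else:
            concentrations[met] = x0

    rxn_ids = set(model.reaction_ids)
    if interventions.bounds_schedule is not None:
        for col in interventions.bounds_schedule.columns:
            rid, _ = _parse_bound_column(str(col))
            if rid not in rxn_ids:
                raise ScheduleError(
                    f"bounds schedule column {col!r} names unknown reaction {rid!r}"
                )
    if interventions.concentration_schedule is not None:
        bad = set(map(str, interventions.concentration_schedule.columns)) - set(exchange_of)
        if bad:
            raise ScheduleError(
                f"concentration schedule names non-exchanged metabolites: {sorted(bad)}"
            )

    original = {r.id: (r.lower_bound, r.upper_bound) for r in model.reactions}
    state = SimulationState(
        time=0.0,
        biomass=float(initial_biomass),
        concentrations=concentrations,
        excess=excess,
        current_bounds=dict(original),
        original_bounds=dict(original),
        excess_exchanged={m: 0.0 for m in excess},
    )
    tracked = [m for m in exchange_of if m not in excess]
    return RunContext(
        model=model,
        biomass_reaction=biomass_id,
        biomass_warned=warned,
        exchange_of=exchange_of,
        tracked=tracked,
        state=state,
        interventions=interventions,
    )


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def interpolate_schedule(sparse: pd.DataFrame, grid: np.ndarray) -> pd.DataFrame:
    """Densify a sparse (knot-based) schedule onto a time grid.

    Each column is linearly interpolated between consecutive knots; values at
    knot times are reproduced exactly.  No extrapolation: a grid point
    outside the knot range is an error.
    """
    knots = np.asarray(sparse.index, dtype=float)
    if np.any(np.diff(knots) <= 0):
        sparse = sparse.sort_index()
        knots = np.asarray(sparse.index, dtype=float)
    grid = np.asarray(grid, dtype=float)
    lo, hi = knots[0], knots[-1]
    if np.any(grid < lo - TIME_MATCH_TOL) or np.any(grid > hi + TIME_MATCH_TOL):
        raise ScheduleError(
            f"grid extends outside the schedule knot range [{lo}, {hi}]; "
            "no extrapolation is performed"
        )
    clipped = np.clip(grid, lo, hi)
    dense = {
        col: np.interp(clipped, knots, sparse[col].to_numpy(dtype=float))
        for col in sparse.columns
    }
    return pd.DataFrame(dense, index=grid)


def _row_at(schedule: pd.DataFrame, t: float) -> pd.Series | None:
    idx = np.asarray(schedule.index, dtype=float)
    hits = np.flatnonzero(np.abs(idx - t) <= TIME_MATCH_TOL)
    if hits.size == 0:
        return None
    return schedule.iloc[hits[0]]


# ---------------------------------------------------------------------------
# Interventions
# ---------------------------------------------------------------------------

def _callback_name(cb) -> str:
    return getattr(cb, "__name__", repr(cb))


def apply_interventions(
    state: SimulationState,
    model: MetabolicModel,
    interventions: InterventionSet,
    t: float,
    dt: float,
    *,
    require_bounds_row: bool = False,
) -> None:
    """Apply the step's interventions in the fixed order (mutates ``state``).

    Order: bounds schedule -> bounds callback -> concentration schedule
    (differential) -> concentration callback (replacement).
    """
    iv = interventions
    if iv.bounds_schedule is not None:
        row = _row_at(iv.bounds_schedule, t)
        if row is None:
            if require_bounds_row:
                raise ScheduleError(
                    f"bounds schedule has no row for t={t} h and "
                    "interpolation is disabled"
                )
        else:
            for col, value in row.items():
                if pd.isna(value):
                    continue
                rid, tag = _parse_bound_column(str(col))
                lb, ub = state.current_bounds[rid]
                if tag == "low":
                    lb = float(value)
                else:
                    ub = float(value)
                state.current_bounds[rid] = (lb, ub)

    if iv.bounds_callback is not None:
        conc_view = _concentration_view(state)
        try:
            result = iv.bounds_callback(model, conc_view, state.last_fluxes, dt)
        except Exception as exc:
            raise ContractError(
                f"bounds callback {_callback_name(iv.bounds_callback)} raised: {exc}"
            ) from exc
        _apply_bounds_mapping(state, model, result, iv.bounds_callback)

    if iv.concentration_schedule is not None:
        row = _row_at(iv.concentration_schedule, t)
        if row is not None:
            for met, delta in row.items():
                met = str(met)
                if pd.isna(delta) or float(delta) == 0.0:
                    continue  # zero means no change
                if met in state.excess:
                    logger.info(
                        "t=%g h: concentration schedule change for EXCESS "
                        "metabolite %s ignored", t, met,
                    )
                    continue
                new = state.concentrations.get(met, 0.0) + float(delta)
                if new < -CONC_TOL:
                    raise ScheduleError(
                        f"t={t} h: removal of {met} drives concentration "
                        f"negative ({new:g} mmol/L)"
                    )
                state.concentrations[met] = max(new, 0.0)

    if iv.concentration_callback is not None:
        conc_view = _concentration_view(state)
        try:
            result = iv.concentration_callback(conc_view)
        except Exception as exc:
            raise ContractError(
                f"concentration callback "
                f"{_callback_name(iv.concentration_callback)} raised: {exc}"
            ) from exc
        _apply_concentration_mapping(state, result, iv.concentration_callback)

    for rid, (lb, ub) in state.current_bounds.items():
        if lb > ub:
            raise ContractError(
                f"t={t} h: interventions left reaction {rid!r} with "
                f"lower bound {lb} > upper bound {ub}"
            )


def _concentration_view(state: SimulationState) -> dict[str, float]:
    view = dict(state.concentrations)
    for met in state.excess:
        view[met] = EXCESS
    return view


def _apply_bounds_mapping(state, model, result, cb) -> None:
    name = _callback_name(cb)
    if not isinstance(result, Mapping):
        raise ContractError(
            f"bounds callback {name} must return a mapping "
            f"reaction -> (lb, ub); got {type(result).__name__}"
        )
    rxn_ids = set(model.reaction_ids)
    for rid, pair in result.items():
        if rid not in rxn_ids:
            raise ContractError(f"bounds callback {name}: unknown reaction {rid!r}")
        try:
            lb, ub = (float(pair[0]), float(pair[1]))
        except (TypeError, ValueError, IndexError) as exc:
            raise ContractError(
                f"bounds callback {name}: value for {rid!r} is not a "
                f"(lb, ub) pair: {pair!r}"
            ) from exc
        state.current_bounds[rid] = (lb, ub)


def _apply_concentration_mapping(state, result, cb) -> None:
    name = _callback_name(cb)
    if not isinstance(result, Mapping):
        raise ContractError(
            f"concentration callback {name} must return a mapping "
            f"metabolite -> mmol/L; got {type(result).__name__}"
        )
    known = set(state.concentrations) | state.excess
    for met, value in result.items():
        if met not in known:
            raise ContractError(
                f"concentration callback {name}: unknown metabolite {met!r}"
            )
        value = float(value)
        if met in state.excess:
            if value >= 0:  # converts an EXCESS metabolite into a tracked one
                state.excess.discard(met)
                state.concentrations[met] = value
            continue
        if value < -CONC_TOL:
            raise ContractError(
                f"concentration callback {name}: negative concentration "
                f"{value:g} for tracked metabolite {met!r}"
            )
        state.concentrations[met] = max(value, 0.0)


# ---------------------------------------------------------------------------
# Step constraints and state update
# ---------------------------------------------------------------------------

def clamp_uptake_bounds(
    state: SimulationState,
    ctx: RunContext,
    dt: float,
    exclude: set[str] | None = None,
) -> BoundsMap:
    """Availability clamp: lb(r) := max(lb(r), -X / (B * dt)).

    Applied only to exchange reactions that are *currently* uptake reactions
    (lower bound < 0 after interventions) of tracked, non-EXCESS metabolites.
    Returns the step's effective bounds without mutating the intervention-
    level bounds, so a recovering concentration relaxes the bound again on
    later steps (never beyond the limit currently in force).
    """
    exclude = exclude or set()
    bounds = dict(state.current_bounds)
    B = state.biomass
    for met, rid in ctx.exchange_of.items():
        if met in state.excess or rid in exclude:
            continue
        lb, ub = bounds[rid]
        if lb < 0:
            X = state.concentrations[met]
            bounds[rid] = (max(lb, -X / (B * dt)), ub)
    return bounds


def _growth_integral(mu: float, dt: float) -> float:
    """integral of exp(mu s) ds over one step, per unit initial biomass."""
    if abs(mu) > MU_TOL:
        return (math.exp(mu * dt) - 1.0) / mu
    return dt


def refine_uptake_bounds(
    state: SimulationState,
    ctx: RunContext,
    bounds: BoundsMap,
    solution: FluxSolution,
    dt: float,
    exclude: set[str] | None = None,
) -> tuple[BoundsMap, bool]:
    """Growth-aware second pass of the availability clamp.

    The pre-solve clamp uses the linear consumption X/(B dt); once the step's
    growth rate mu is known, consumption actually follows the exponential
    integral B (exp(mu dt) - 1)/mu, which exceeds the linear one for mu > 0.
    This pass re-tightens any uptake bound that would overdraw its pool under
    the realised mu; the caller re-solves until no bound moves (tightening
    uptake can only lower mu, so the iteration converges).
    """
    exclude = exclude or set()
    mu = float(solution.fluxes[ctx.biomass_reaction])
    g = _growth_integral(mu, dt) * state.biomass
    tightened = False
    out = dict(bounds)
    for met, rid in ctx.exchange_of.items():
        if met in state.excess or rid in exclude:
            continue
        lb, ub = out[rid]
        if lb < 0:
            limit = -state.concentrations[met] / g
            if lb < limit - 1e-15:
                out[rid] = (limit, ub)
                tightened = True
    return out, tightened


def update_state(
    state: SimulationState,
    ctx: RunContext,
    solution: FluxSolution,
    dt: float,
) -> None:
    """Integrate one step forward (mutates ``state``).

    Growth is read from the biomass reaction flux mu (1/h), *not* from the
    LP objective: B' = B exp(mu dt).  Each tracked concentration follows the
    analytic form X' = X + v B (exp(mu dt) - 1)/mu, degrading to the Euler
    form X' = X + v B dt when |mu| <= 1e-9.
    """
    if not solution.optimal:
        raise ConfigurationError("update_state requires an optimal solution")
    mu = float(solution.fluxes[ctx.biomass_reaction])
    B = state.biomass
    if abs(mu) > MU_TOL:
        growth_integral = B * (math.exp(mu * dt) - 1.0) / mu
    else:
        growth_integral = B * dt
    for met, rid in ctx.exchange_of.items():
        v = float(solution.fluxes[rid])
        if met in state.excess:
            state.excess_exchanged[met] = (
                state.excess_exchanged.get(met, 0.0) + v * growth_integral
            )
            continue
        new = state.concentrations[met] + v * growth_integral
        if new < -CONC_TOL:
            raise IntegrationError(
                f"t={state.time + dt:g} h: concentration of {met} driven to "
                f"{new:g} mmol/L (< -1e-9); uptake clamping failed"
            )
        state.concentrations[met] = max(new, 0.0)
    state.biomass = B * math.exp(mu * dt)
    state.time += dt
    state.last_fluxes = solution


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def run_adaptive_dfba(
    model: MetabolicModel,
    initial_concentrations: Mapping[str, float],
    initial_biomass: float,
    t_end: float,
    dt: float = 1.0,
    interventions: InterventionSet | None = None,
    solver: str = "fba",
    fva: float | None = None,
    objective_fraction: float = 1.0,
    exclude_uptake: set[str] | None = None,
    biomass_reaction: str | None = None,
    interpolate_schedules: bool = True,
) -> Trajectory:
    """Run the adaptive DFBA main loop and assemble the trajectory.

    Parameters
    ----------
    solver:
        ``"fba"`` (default) or ``"mtf"`` (total-flux minimisation at the
        FBA optimum, a tie-break against alternate optima).
    fva:
        If a fraction in (0, 1] is given, per-step FVA ranges at that
        objective fraction are recorded (substantially slower; off by
        default).
    exclude_uptake:
        Exchange reaction ids never subjected to the availability clamp.
    interpolate_schedules:
        Densify a sparse bounds schedule by linear interpolation between its
        knots.  When False, the schedule must carry a row for every grid
        time (a missing row is an error).

    An infeasible step ends the run early; the partial trajectory is
    returned with ``termination_reason`` set — this is a result, not an
    exception.
    """
    if not (t_end > 0):
        raise ConfigurationError(f"t_end must be positive, got {t_end}")
    if solver not in ("fba", "mtf"):
        raise ConfigurationError(f"solver must be 'fba' or 'mtf', got {solver!r}")
    ctx = validate_setup(
        model, initial_concentrations, initial_biomass, interventions,
        dt=dt, biomass_reaction=biomass_reaction,
    )
    iv = ctx.interventions
    n_steps = int(math.floor(t_end / dt + TIME_MATCH_TOL))
    grid = np.array([i * dt for i in range(n_steps + 1)])

    require_row = False
    if iv.bounds_schedule is not None:
        if interpolate_schedules:
            iv = InterventionSet(
                bounds_schedule=interpolate_schedule(iv.bounds_schedule, grid),
                bounds_callback=iv.bounds_callback,
                concentration_schedule=iv.concentration_schedule,
                concentration_callback=iv.concentration_callback,
            )
        else:
            require_row = True

    state = ctx.state
    conc_order = list(ctx.exchange_of)
    rec_times: list[float] = []
    rec_biomass: list[float] = []
    rec_conc: list[list[float]] = []
    rec_status: list[str] = []
    rec_fluxes: list[pd.Series] = []
    fva_min_rows: list[pd.Series] = []
    fva_max_rows: list[pd.Series] = []
    termination = "completed"

    for i, t in enumerate(grid):
        apply_interventions(
            state, model, iv, float(t), dt, require_bounds_row=require_row
        )
        step_bounds = clamp_uptake_bounds(state, ctx, dt, exclude=exclude_uptake)
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug("t=%g h: bounds in force %s", t, step_bounds)
        def _solve(b: BoundsMap) -> FluxSolution:
            if solver == "mtf":
                return solve_mtf(model, objective_fraction, bounds=b)
            return solve_fba(model, bounds=b)

        solution = _solve(step_bounds)
        # growth-aware refinement: with mu known, re-tighten any uptake
        # bound whose pool the exponential consumption would overdraw
        for _ in range(25):
            if not solution.optimal:
                break
            step_bounds, tightened = refine_uptake_bounds(
                state, ctx, step_bounds, solution, dt, exclude=exclude_uptake
            )
            if not tightened:
                break
            solution = _solve(step_bounds)

        rec_times.append(float(t))
        rec_biomass.append(state.biomass)
        rec_conc.append(state.snapshot_concentrations(conc_order))
        rec_status.append(solution.status)
        if solution.optimal:
            rec_fluxes.append(solution.fluxes)
        else:
            rec_fluxes.append(pd.Series(np.nan, index=model.reaction_ids))

        if fva is not None and solution.optimal:
            fva_res = solve_fva(model, fva, bounds=step_bounds)
            fva_min_rows.append(fva_res.min_flux)
            fva_max_rows.append(fva_res.max_flux)

        if not solution.optimal:
            termination = f"{solution.status} LP at t={t:g} h"
            logger.info("simulation ended prematurely: %s", termination)
            break
        if i == len(grid) - 1:
            break
        update_state(state, ctx, solution, dt)

    times = np.array(rec_times)
    conc = pd.DataFrame(rec_conc, columns=conc_order)
    # metabolites in EXCESS over the whole run keep the sentinel in output
    always_excess = frozenset(
        m for m in conc_order if conc[m].isna().all() and m in state.excess | set(state.excess_exchanged)
    )
    fluxes = pd.DataFrame(rec_fluxes).reset_index(drop=True)
    traj = Trajectory(
        times=times,
        biomass=np.array(rec_biomass),
        concentrations=conc,
        step_status=rec_status,
        excess_metabolites=always_excess,
        fluxes=fluxes,
        termination_reason=termination,
        fva_min=pd.DataFrame(fva_min_rows).reset_index(drop=True) if fva_min_rows else None,
        fva_max=pd.DataFrame(fva_max_rows).reset_index(drop=True) if fva_max_rows else None,
    )
    if state.excess_exchanged:
        for met, total in sorted(state.excess_exchanged.items()):
            logger.info(
                "cumulative exchange of EXCESS metabolite %s: %g mmol/L", met, total
            )
    return traj
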