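"""Model and trajectory input/output.

Two model dialects are supported: SBML Level 3 with fbc flux bounds and
objective (the interchange standard, read and written through COBRApy), and a
tabular TSV dialect (columns ``reaction  name  equation  lower_bound
upper_bound  objective``) so that test fixtures need no XML authoring.

Conventions fixed here and relied on everywhere else:

* Flux units are mmol/gDW/h, concentrations mmol/L, biomass gDW/L, time h.
* Infinite bounds are encoded as ``±INF_BOUND`` (1e6) to keep LPs bounded.
* An exchange reaction is a reaction touching exactly one metabolite, written
  so that the metabolite is the sole reactant: positive flux secretes to the
  medium, negative flux takes up.  Models written the other way round are
  flipped on load (stoichiometry, bounds and objective coefficient negated)
  with a log entry.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    FormatError,
    ModelValidationError,
    ReactionLookupError,
)

logger = logging.getLogger("adfba.model_io")

#: Stand-in for an unbounded flux, mmol/gDW/h.
INF_BOUND = 1.0e6

#: Sentinel concentration for metabolites available in unlimited excess
#: (initialised with a negative concentration).  Stored as -inf internally
#: and written as the literal string ``EXCESS`` in trajectory files.
EXCESS = float("-inf")

_EXCESS_TOKEN = "EXCESS"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str = ""
    #: metabolite id -> signed stoichiometric coefficient
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -INF_BOUND
    upper_bound: float = INF_BOUND
    objective_coefficient: float = 0.0


@dataclass
class MetabolicModel:
    """Stoichiometry, bounds and objective of a constraint-based model."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str | None = None
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rid: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rid)
        except StopIteration:
            raise ReactionLookupError(f"reaction {rid!r} not in model {self.id!r}")

    def stoichiometric_matrix(self) -> pd.DataFrame:
        """Metabolites x reactions matrix S."""
        S = pd.DataFrame(
            0.0, index=self.metabolite_ids, columns=self.reaction_ids
        )
        for rxn in self.reactions:
            for met, coef in rxn.stoichiometry.items():
                S.loc[met, rxn.id] = coef
        return S

    def validate(self) -> None:
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError(f"duplicate metabolite ids in {self.id!r}")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError(f"duplicate reaction ids in {self.id!r}")
        known = set(met_ids)
        for rxn in self.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lower_bound {rxn.lower_bound} > "
                    f"upper_bound {rxn.upper_bound}"
                )
            unknown = set(rxn.stoichiometry) - known
            if unknown:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolites "
                    f"{sorted(unknown)}"
                )
        if self.biomass_reaction_id is not None and (
            self.biomass_reaction_id not in set(rxn_ids)
        ):
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            biomass_reaction_id=self.biomass_reaction_id,
            id=self.id,
        )


@dataclass
class Trajectory:
    """Full time series returned by a simulation.

    ``concentrations`` holds NaN in the columns of EXCESS metabolites (their
    identity is kept in ``excess_metabolites``); ``fluxes`` holds NaN on rows
    where the LP was not solved (an infeasible terminal step).
    """

    times: np.ndarray
    biomass: np.ndarray
    concentrations: pd.DataFrame
    step_status: list[str]
    excess_metabolites: frozenset[str] = frozenset()
    fluxes: pd.DataFrame | None = None
    termination_reason: str = "completed"
    fva_min: pd.DataFrame | None = None
    fva_max: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.biomass) == len(self.concentrations) == len(self.step_status) == n):
            raise ModelValidationError("trajectory arrays disagree on time grid length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ModelValidationError("trajectory time grid must be strictly increasing")

    @property
    def completed(self) -> bool:
        return self.termination_reason == "completed"


# ---------------------------------------------------------------------------
# Exchange / biomass identification
# ---------------------------------------------------------------------------

def identify_exchange_reactions(model: MetabolicModel) -> set[str]:
    """Reactions touching exactly one metabolite (boundary reactions).

    Positive flux secretes the metabolite to the medium, negative flux takes
    it up (models are normalised to this orientation on load).
    """
    return {r.id for r in model.reactions if len(r.stoichiometry) == 1}


def exchanged_metabolite(model: MetabolicModel, rid: str) -> str:
    """The single metabolite moved by exchange reaction ``rid``."""
    stoich = model.reaction(rid).stoichiometry
    if len(stoich) != 1:
        raise ModelValidationError(f"{rid!r} is not an exchange reaction")
    return next(iter(stoich))


def find_biomass_reaction(
    model: MetabolicModel, hint: str | None = None
) -> tuple[str, bool]:
    """Resolve the biomass reaction; returns ``(reaction_id, warned)``.

    Resolution order: explicit hint; unique id/name match on "biomass"
    (preferring a positive objective coefficient on ties); first reaction
    carrying a nonzero objective coefficient, with the warning flag set.
    """
    if hint is not None:
        if hint in set(model.reaction_ids):
            return hint, False
        raise ReactionLookupError(f"biomass hint {hint!r} not in model {model.id!r}")
    candidates = [
        r for r in model.reactions
        if "biomass" in r.id.lower() or "biomass" in r.name.lower()
    ]
    if candidates:
        if len(candidates) > 1:
            preferred = [r for r in candidates if r.objective_coefficient > 0]
            if preferred:
                candidates = preferred
        return candidates[0].id, False
    for rxn in model.reactions:
        if rxn.objective_coefficient != 0:
            logger.warning(
                "no biomass-named reaction in %s; using first objective "
                "reaction %s as biomass", model.id, rxn.id,
            )
            return rxn.id, True
    raise ConfigurationError(
        f"model {model.id!r} has no biomass candidate: no biomass-named "
        "reaction and no nonzero objective coefficient"
    )


def _normalise_exchanges(reactions: list[Reaction], model_id: str) -> list[Reaction]:
    """Flip single-metabolite reactions written metabolite-as-product."""
    out = []
    for rxn in reactions:
        if len(rxn.stoichiometry) == 1:
            met, coef = next(iter(rxn.stoichiometry.items()))
            if coef > 0:
                logger.info(
                    "model %s: flipping exchange %s to metabolite-as-reactant "
                    "orientation", model_id, rxn.id,
                )
                rxn = replace(
                    rxn,
                    stoichiometry={met: -coef},
                    lower_bound=-rxn.upper_bound,
                    upper_bound=-rxn.lower_bound,
                    objective_coefficient=-rxn.objective_coefficient,
                )
        out.append(rxn)
    return out


def _clip_bound(value: float) -> float:
    if value is None or math.isnan(value):
        raise ModelValidationError("missing flux bound")
    return float(np.clip(value, -INF_BOUND, INF_BOUND))


# ---------------------------------------------------------------------------
# SBML dialect (through COBRApy)
# ---------------------------------------------------------------------------

def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML Level 3 (fbc) model file."""
    import cobra.io
    from cobra.io.sbml import CobraSBMLError

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except (CobraSBMLError, OSError) as exc:
        raise FormatError(f"cannot parse SBML file {path!r}: {exc}") from exc
    mets = [
        Metabolite(m.id, m.name or "", m.compartment or "")
        for m in cmodel.metabolites
    ]
    reactions = []
    for rxn in cmodel.reactions:
        reactions.append(
            Reaction(
                id=rxn.id,
                name=rxn.name or "",
                stoichiometry={m.id: float(c) for m, c in rxn.metabolites.items()},
                lower_bound=_clip_bound(rxn.lower_bound),
                upper_bound=_clip_bound(rxn.upper_bound),
                objective_coefficient=float(rxn.objective_coefficient),
            )
        )
    reactions = _normalise_exchanges(reactions, cmodel.id or str(path))
    try:
        return MetabolicModel(mets, reactions, id=cmodel.id or "model")
    except ModelValidationError as exc:
        raise ModelValidationError(f"{path}: {exc}") from exc


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML Level 3 with fbc bounds and objective."""
    import cobra
    import cobra.io

    cmodel = cobra.Model(model.id)
    cmets = {}
    for met in model.metabolites:
        cm = cobra.Metabolite(
            met.id, name=met.name, compartment=met.compartment or "c"
        )
        cmets[met.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    objective = {}
    for rxn in model.reactions:
        cr = cobra.Reaction(
            rxn.id, name=rxn.name,
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
        )
        cmodel.add_reactions([cr])
        cr.add_metabolites({cmets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.objective_coefficient != 0:
            objective[cr] = rxn.objective_coefficient
    cmodel.objective = {r: c for r, c in objective.items()}
    cobra.io.write_sbml_model(cmodel, str(path))


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)$")
_ARROWS = ("<->", "<=>", "->", "=>")


def _parse_equation(equation: str, rid: str) -> dict[str, float]:
    """Parse ``"A + 2 B -> 0.5 C"``; either side may be empty (exchanges)."""
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise FormatError(f"reaction {rid!r}: no arrow in equation {equation!r}")
    left, right = equation.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            m = _TERM_RE.match(term)
            if m is None:
                raise FormatError(f"reaction {rid!r}: bad term {term!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}


def _format_equation(stoich: dict[str, float]) -> str:
    def fmt(items):
        parts = []
        for met, coef in items:
            coef = abs(coef)
            parts.append(met if coef == 1 else f"{coef:g} {met}")
        return " + ".join(parts)

    left = fmt([(m, c) for m, c in stoich.items() if c < 0])
    right = fmt([(m, c) for m, c in stoich.items() if c > 0])
    return f"{left} -> {right}".strip()


def read_tabular_model(path: str) -> MetabolicModel:
    """Read the TSV model dialect.

    Columns: ``reaction``, ``name`` (optional), ``equation``,
    ``lower_bound``, ``upper_bound``, ``objective``.  Metabolites are
    implied by the equations; direction is carried by the bounds.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse tabular model {path!r}: {exc}") from exc
    required = {"reaction", "equation", "lower_bound", "upper_bound", "objective"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    reactions = []
    met_ids: dict[str, None] = {}
    for _, row in df.iterrows():
        rid = str(row["reaction"])
        stoich = _parse_equation(str(row["equation"]), rid)
        for met in stoich:
            met_ids.setdefault(met)
        reactions.append(
            Reaction(
                id=rid,
                name="" if "name" not in df.columns or pd.isna(row.get("name")) else str(row["name"]),
                stoichiometry=stoich,
                lower_bound=_clip_bound(float(row["lower_bound"])),
                upper_bound=_clip_bound(float(row["upper_bound"])),
                objective_coefficient=float(row["objective"]),
            )
        )
    reactions = _normalise_exchanges(reactions, str(path))
    mets = [Metabolite(mid) for mid in met_ids]
    try:
        return MetabolicModel(mets, reactions, id=str(path))
    except ModelValidationError as exc:
        raise ModelValidationError(f"{path}: {exc}") from exc


def write_tabular_model(model: MetabolicModel, path: str) -> None:
    rows = []
    for rxn in model.reactions:
        rows.append(
            {
                "reaction": rxn.id,
                "name": rxn.name,
                "equation": _format_equation(rxn.stoichiometry),
                "lower_bound": rxn.lower_bound,
                "upper_bound": rxn.upper_bound,
                "objective": rxn.objective_coefficient,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_model(path: str) -> MetabolicModel:
    """Dispatch on extension: ``.xml``/``.sbml`` -> SBML, else tabular."""
    p = str(path)
    if p.endswith((".xml", ".sbml")):
        return read_sbml(p)
    return read_tabular_model(p)


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def read_schedule(path: str) -> pd.DataFrame:
    """Read a delimited schedule table: first column ``time``, then values.

    Used both for bounds schedules (columns ``<reaction>[low]`` /
    ``<reaction>[upp]``) and concentration schedules (columns = metabolite
    ids, differential values).
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse schedule {path!r}: {exc}") from exc
    if df.columns[0] != "time":
        raise FormatError(f"{path}: first schedule column must be 'time'")
    df = df.set_index("time")
    df.index = df.index.astype(float)
    return df


def write_schedule(schedule: pd.DataFrame, path: str) -> None:
    schedule.rename_axis("time").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str, include_fluxes: bool = True) -> None:
    """Write a trajectory as TSV: ``time  biomass  status`` then one column
    per tracked metabolite, then (optionally) ``flux:<reaction>`` columns.

    EXCESS metabolite cells are written as the literal ``EXCESS``; the
    termination reason goes into a leading comment line.
    """
    df = pd.DataFrame({"time": traj.times, "biomass": traj.biomass})
    df["status"] = traj.step_status
    for met in traj.concentrations.columns:
        if met in traj.excess_metabolites:
            df[met] = _EXCESS_TOKEN
        else:
            df[met] = traj.concentrations[met].to_numpy()
    if include_fluxes and traj.fluxes is not None:
        for rid in traj.fluxes.columns:
            df[f"flux:{rid}"] = traj.fluxes[rid].to_numpy()
    buf = io.StringIO()
    buf.write(f"# termination_reason: {traj.termination_reason}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trajectory(path: str) -> Trajectory:
    termination = "completed"
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines(True)
    body = []
    for line in lines:
        if line.startswith("# termination_reason:"):
            termination = line.split(":", 1)[1].strip()
        elif not line.startswith("#"):
            body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    for col in ("time", "biomass", "status"):
        if col not in df.columns:
            raise FormatError(f"{path}: trajectory lacks column {col!r}")
    flux_cols = [c for c in df.columns if c.startswith("flux:")]
    met_cols = [
        c for c in df.columns
        if c not in ("time", "biomass", "status") and not c.startswith("flux:")
    ]
    excess = frozenset(
        c for c in met_cols if (df[c].astype(str) == _EXCESS_TOKEN).all()
    )
    conc = pd.DataFrame(index=df.index)
    for c in met_cols:
        conc[c] = np.nan if c in excess else df[c].astype(float).to_numpy()
    fluxes = None
    if flux_cols:
        fluxes = df[flux_cols].copy()
        fluxes.columns = [c.split(":", 1)[1] for c in flux_cols]
    times = df["time"].to_numpy(dtype=float)
    conc.index = df.index
    return Trajectory(
        times=times,
        biomass=df["biomass"].to_numpy(dtype=float),
        concentrations=conc,
        step_status=[str(s) for s in df["status"]],
        excess_metabolites=excess,
        fluxes=fluxes,
        termination_reason=termination,
    )
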