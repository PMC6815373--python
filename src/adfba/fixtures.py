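"""Deterministic toy models and synthetic tables for exercising the engine.

The toy networks are stand-ins for genome-scale scenarios: each kind
guarantees a qualitative behaviour under its default parameters.

* ``minimal-chain`` — substrate uptake, one conversion, one export carrying
  the objective; the smallest solvable model (FBA optimum 10).
* ``diauxic`` — glucose-like primary substrate, an oxygen-capped respiratory
  pathway, a fermentative pathway excreting a by-product that is re-consumed
  once glucose is exhausted: a two-phase growth curve with a single sign
  change of the by-product exchange flux (an acetate-overflow/L-alanine-
  switch analogue).
* ``secretion-conflict`` — a protein-secretion exchange whose synthesis
  drains the same precursor pool as biomass plus a parameterised ATP cost;
  growth outcompetes secretion unless the secretion lower bound is forced.
* ``futile-cycle`` — the minimal chain plus a two-reaction internal loop
  that can carry arbitrary flux; total-flux minimisation zeroes it.
* ``parallel-paths`` — the conversion duplicated into two equivalent routes,
  giving genuinely alternate optima (FVA ranges (0, 10) on each route).

Fixture scale stays below 25 reactions so brute-force LP oracles remain
feasible in the test suite.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .model_io import INF_BOUND, MetabolicModel, Metabolite, Reaction

FIXTURE_KINDS = (
    "minimal-chain",
    "diauxic",
    "secretion-conflict",
    "futile-cycle",
    "parallel-paths",
)

ToyFixture = tuple[MetabolicModel, dict[str, float], float]


def _model(mid: str, reactions: list[Reaction]) -> MetabolicModel:
    mets = sorted({m for r in reactions for m in r.stoichiometry})
    return MetabolicModel([Metabolite(m) for m in mets], reactions, id=mid)


def _chain_reactions(uptake_lb: float = -10.0) -> list[Reaction]:
    return [
        Reaction("EX_A", stoichiometry={"A": -1.0}, lower_bound=uptake_lb,
                 upper_bound=0.0),
        Reaction("R_AB", stoichiometry={"A": -1.0, "B": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction("EX_B", stoichiometry={"B": -1.0}, lower_bound=0.0,
                 upper_bound=1000.0, objective_coefficient=1.0),
    ]


def make_toy_model(kind: str, **params) -> ToyFixture:
    """Build a toy model plus matching initial concentrations and biomass.

    Returns ``(model, initial_concentrations, initial_biomass)``; the
    concentrations follow the engine conventions (0 = absent, negative =
    EXCESS).  Parameters vary by kind, see the module docstring; common ones
    are ``initial_biomass`` (default 0.05 gDW/L, sensible range 0.01-0.1).
    """
    biomass0 = float(params.pop("initial_biomass", 0.05))
    if not (biomass0 > 0):
        raise ConfigurationError("initial_biomass must be positive")

    if kind == "minimal-chain":
        uptake_lb = float(params.pop("uptake_lb", -10.0))
        _reject_extras(kind, params)
        model = _model("minimal_chain", _chain_reactions(uptake_lb))
        return model, {"A": 10.0}, biomass0

    if kind == "diauxic":
        glc0 = float(params.pop("glc0", 10.0))
        o2_cap = float(params.pop("o2_cap", 4.0))
        y_ferm = float(params.pop("y_ferm", 0.05))
        y_resp_glc = float(params.pop("y_resp_glc", 0.20))
        y_resp_byp = float(params.pop("y_resp_byp", 0.06))
        _reject_extras(kind, params)
        reactions = [
            Reaction("EX_glc", stoichiometry={"glc": -1.0},
                     lower_bound=-10.0, upper_bound=0.0),
            Reaction("EX_byp", stoichiometry={"byp": -1.0},
                     lower_bound=-10.0, upper_bound=1000.0),
            Reaction("EX_o2", stoichiometry={"o2": -1.0},
                     lower_bound=-o2_cap, upper_bound=0.0),
            Reaction("R_ferm",
                     stoichiometry={"glc": -1.0, "byp": 1.0, "BM": y_ferm},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction("R_resp_glc",
                     stoichiometry={"glc": -1.0, "o2": -2.0, "BM": y_resp_glc},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction("R_resp_byp",
                     stoichiometry={"byp": -1.0, "o2": -1.0, "BM": y_resp_byp},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction("Biomass", name="biomass",
                     stoichiometry={"BM": -1.0},
                     lower_bound=0.0, upper_bound=1000.0,
                     objective_coefficient=1.0),
        ]
        model = _model("diauxic", reactions)
        conc = {"glc": glc0, "byp": 0.0, "o2": -1.0}  # o2 in EXCESS (flux-capped)
        return model, conc, biomass0

    if kind == "secretion-conflict":
        glc0 = float(params.pop("glc0", 10.0))
        atp_cost = float(params.pop("atp_cost", 2.0))
        biomass_scale = float(params.pop("biomass_scale", 20.0))
        _reject_extras(kind, params)
        if atp_cost < 0:
            raise ConfigurationError("atp_cost must be non-negative")
        reactions = [
            Reaction("EX_glc", stoichiometry={"glc": -1.0},
                     lower_bound=-10.0, upper_bound=0.0),
            Reaction("R_cat",
                     stoichiometry={"glc": -1.0, "prec": 1.0, "atp": 2.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction("Biomass", name="biomass",
                     stoichiometry={"prec": -biomass_scale, "atp": -biomass_scale},
                     lower_bound=0.0, upper_bound=1000.0,
                     objective_coefficient=1.0),
            Reaction("R_protsyn",
                     stoichiometry={"prec": -1.0, "atp": -atp_cost, "prot": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction("EX_prot", stoichiometry={"prot": -1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction("R_atpm", stoichiometry={"atp": -1.0},
                     lower_bound=0.0, upper_bound=1000.0),
        ]
        model = _model("secretion_conflict", reactions)
        return model, {"glc": glc0, "prot": 0.0}, biomass0

    if kind == "futile-cycle":
        _reject_extras(kind, params)
        reactions = _chain_reactions() + [
            Reaction("R_cyc_fwd", stoichiometry={"B": -1.0, "C": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction("R_cyc_rev", stoichiometry={"C": -1.0, "B": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
        ]
        model = _model("futile_cycle", reactions)
        return model, {"A": 10.0}, biomass0

    if kind == "parallel-paths":
        _reject_extras(kind, params)
        reactions = [
            Reaction("EX_A", stoichiometry={"A": -1.0}, lower_bound=-10.0,
                     upper_bound=0.0),
            Reaction("R1", stoichiometry={"A": -1.0, "B": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction("R2", stoichiometry={"A": -1.0, "B": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction("EX_B", stoichiometry={"B": -1.0}, lower_bound=0.0,
                     upper_bound=1000.0, objective_coefficient=1.0),
        ]
        model = _model("parallel_paths", reactions)
        return model, {"A": 10.0}, biomass0

    raise ConfigurationError(
        f"unknown fixture kind {kind!r}; choose one of {FIXTURE_KINDS}"
    )


def _reject_extras(kind: str, params: Mapping) -> None:
    if params:
        raise ConfigurationError(
            f"unknown parameters for fixture kind {kind!r}: {sorted(params)}"
        )


def make_random_scenario(seed: int) -> tuple[str, ToyFixture, float, float]:
    """A randomised but always-valid run configuration for stress tests.

    Returns ``(kind, (model, concentrations, biomass0), dt, t_end)`` with
    initial concentrations, biomass, and step size drawn from documented
    fixture ranges.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    kind = str(rng.choice(["minimal-chain", "diauxic", "secretion-conflict"]))
    biomass0 = float(rng.uniform(0.01, 0.1))
    if kind == "diauxic":
        model, conc, _ = make_toy_model(
            kind,
            glc0=float(rng.uniform(2.0, 15.0)),
            o2_cap=float(rng.uniform(1.0, 6.0)),
            initial_biomass=biomass0,
        )
    elif kind == "secretion-conflict":
        model, conc, _ = make_toy_model(
            kind,
            glc0=float(rng.uniform(2.0, 15.0)),
            atp_cost=float(rng.uniform(0.5, 5.0)),
            initial_biomass=biomass0,
        )
    else:
        model, conc, _ = make_toy_model(kind, initial_biomass=biomass0)
        conc = {"A": float(rng.uniform(1.0, 15.0))}
    dt = float(rng.choice([0.25, 0.5, 1.0]))
    t_end = float(rng.choice([4.0, 8.0, 12.0]))
    return kind, (model, conc, biomass0), dt, t_end


def make_synthetic_table(
    n_vars: int,
    n_times: int,
    planted: Mapping[str, float] | None = None,
    noise_sigma: float = 1.0,
    seed: int | None = None,
    outcome_name: str = "outcome",
) -> pd.DataFrame:
    """Synthetic variables-by-time table with an optionally planted signal.

    ``n_vars`` decoy variables ``V1..Vn`` are independent standard-normal
    draws; the outcome column is ``sum(coef * V)`` over ``planted`` plus
    N(0, ``noise_sigma``) noise (pure noise when ``planted`` is None).
    Reproducible under ``seed``.
    """
    if n_vars < 2:
        raise ConfigurationError("n_vars must be >= 2")
    if n_times < 8:
        raise ConfigurationError("n_times must be >= 8")
    if noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    names = [f"V{i + 1}" for i in range(n_vars)]
    data = {name: rng.standard_normal(n_times) for name in names}
    table = pd.DataFrame(data, index=np.arange(n_times, dtype=float))
    planted = planted or {}
    unknown = set(planted) - set(names)
    if unknown:
        raise ConfigurationError(f"planted formula names unknown variables: {sorted(unknown)}")
    outcome = np.zeros(n_times)
    for name, coef in planted.items():
        outcome = outcome + float(coef) * table[name].to_numpy()
    outcome = outcome + rng.normal(0.0, noise_sigma, n_times)
    table[outcome_name] = outcome
    table.index.name = "time"
    return table
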