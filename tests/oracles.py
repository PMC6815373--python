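"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own LP and integration code paths:
the vertex-enumeration FBA oracle works from first principles on the
polytope, and the classic DFBA oracle drives COBRApy (GLPK backend) with
its own loop, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from adfba.model_io import MetabolicModel, Metabolite, Reaction


def brute_force_fba_objective(model: MetabolicModel, tol: float = 1e-9) -> float:
    """Max objective by enumerating candidate vertices of {Sv=0, lb<=v<=ub}.

    Every LP optimum sits at a vertex where each variable is either fixed at
    a bound or solved uniquely from the steady-state equations; with n <= 6
    reactions, enumerating all bound assignments is cheap.
    """
    S = model.stoichiometric_matrix().to_numpy()
    n = len(model.reactions)
    lbs = np.array([r.lower_bound for r in model.reactions])
    ubs = np.array([r.upper_bound for r in model.reactions])
    c = np.array([r.objective_coefficient for r in model.reactions])
    best = -np.inf
    for assignment in itertools.product((0, 1, 2), repeat=n):
        fixed_idx = [i for i, a in enumerate(assignment) if a != 2]
        free_idx = [i for i, a in enumerate(assignment) if a == 2]
        v = np.zeros(n)
        for i in fixed_idx:
            v[i] = lbs[i] if assignment[i] == 0 else ubs[i]
        if free_idx:
            A = S[:, free_idx]
            b = -S[:, fixed_idx] @ v[fixed_idx] if fixed_idx else np.zeros(S.shape[0])
            if np.linalg.matrix_rank(A) < len(free_idx):
                continue  # free block not uniquely determined: not a vertex
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            v[free_idx] = sol
        if np.max(np.abs(S @ v)) > tol:
            continue
        if np.any(v < lbs - tol) or np.any(v > ubs + tol):
            continue
        best = max(best, float(c @ v))
    return best


def random_small_network(seed: int, max_reactions: int = 12) -> MetabolicModel:
    """Seeded random network with finite integer bounds; v=0 always feasible."""
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(2, 5))
    n_rxns = int(rng.integers(3, max_reactions + 1))
    mets = [Metabolite(f"m{i}") for i in range(n_mets)]
    reactions = []
    bound_choices = [(-10.0, 0.0), (0.0, 10.0), (-10.0, 10.0), (-5.0, 5.0)]
    for j in range(n_rxns):
        coeffs = rng.integers(-2, 3, size=n_mets)
        stoich = {f"m{i}": float(c) for i, c in enumerate(coeffs) if c != 0}
        if not stoich:
            stoich = {f"m{int(rng.integers(0, n_mets))}": 1.0}
        lb, ub = bound_choices[int(rng.integers(0, len(bound_choices)))]
        reactions.append(
            Reaction(f"r{j}", stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
        )
    obj = int(rng.integers(0, n_rxns))
    reactions[obj] = Reaction(
        reactions[obj].id,
        stoichiometry=reactions[obj].stoichiometry,
        lower_bound=reactions[obj].lower_bound,
        upper_bound=reactions[obj].upper_bound,
        objective_coefficient=1.0,
    )
    return MetabolicModel(mets, reactions, id=f"random_{seed}")


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {m.id: cobra.Metabolite(m.id, compartment="c") for m in model.metabolites}
    cm.add_metabolites(list(mets.values()))
    objective = {}
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        if r.objective_coefficient:
            objective[cr] = r.objective_coefficient
    cm.objective = objective
    return cm


def classic_dfba_oracle(
    model: MetabolicModel,
    initial_concentrations: dict[str, float],
    initial_biomass: float,
    t_end: float,
    dt: float,
    biomass_id: str,
    exchange_of: dict[str, str],
):
    """Classic SOA-DFBA loop on COBRApy/GLPK, independent of the package.

    Scheme: availability clamp lb >= -X/(B dt), growth-aware re-tightening
    against the exponential consumption integral, then the exponential
    biomass/concentration update with growth read from ``biomass_id``.
    Returns (times, biomass, concentrations DataFrame).
    """
    cm = _to_cobra(model)
    conc = dict(initial_concentrations)
    B = initial_biomass
    orig = {r.id: (r.lower_bound, r.upper_bound) for r in cm.reactions}
    times, biomass, concs = [], [], []
    n = int(round(t_end / dt))

    def growth_integral(mu: float) -> float:
        return (math.exp(mu * dt) - 1.0) / mu if abs(mu) > 1e-9 else dt

    for i in range(n + 1):
        for met, rid in exchange_of.items():
            lb, ub = orig[rid]
            if lb < 0:
                lb = max(lb, -conc[met] / (B * dt))
            cm.reactions.get_by_id(rid).bounds = (lb, ub)
        sol = cm.optimize()
        assert sol.status == "optimal", f"oracle LP {sol.status} at step {i}"
        for _ in range(25):
            g = B * growth_integral(float(sol.fluxes[biomass_id]))
            moved = False
            for met, rid in exchange_of.items():
                lb, ub = cm.reactions.get_by_id(rid).bounds
                if lb < 0:
                    limit = -conc[met] / g
                    if lb < limit - 1e-15:
                        cm.reactions.get_by_id(rid).bounds = (limit, ub)
                        moved = True
            if not moved:
                break
            sol = cm.optimize()
        times.append(i * dt)
        biomass.append(B)
        concs.append(dict(conc))
        if i == n:
            break
        mu = float(sol.fluxes[biomass_id])
        g = B * growth_integral(mu)
        for met, rid in exchange_of.items():
            conc[met] = max(conc[met] + float(sol.fluxes[rid]) * g, 0.0)
        B *= math.exp(mu * dt)
    return np.array(times), np.array(biomass), pd.DataFrame(concs)
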