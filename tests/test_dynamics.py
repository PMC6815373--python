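"""Engine behaviour: setup semantics, interventions, clamping, integration."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from adfba import (
    InterventionSet,
    MetabolicModel,
    interpolate_schedule,
    run_adaptive_dfba,
    validate_setup,
)
from adfba.dynamics import apply_interventions, clamp_uptake_bounds, update_state
from adfba.exceptions import ConfigurationError, ContractError, ScheduleError
from adfba.lp_core import FluxSolution
from adfba.model_io import write_trajectory

from oracles import classic_dfba_oracle


class TestValidateSetup:
    def test_zero_concentration_marks_absent_substrate(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        ctx = validate_setup(model, conc, b0, dt=1.0)
        assert "byp" in ctx.tracked
        assert ctx.state.concentrations["byp"] == 0.0
        bounds = clamp_uptake_bounds(ctx.state, ctx, 1.0)
        assert bounds["EX_byp"][0] == 0.0  # no uptake of an absent substrate

    def test_negative_concentration_marks_excess(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        ctx = validate_setup(model, conc, b0, dt=1.0)
        assert "o2" in ctx.state.excess
        bounds = clamp_uptake_bounds(ctx.state, ctx, 1.0)
        assert bounds["EX_o2"] == (-4.0, 0.0)  # never clamped

    def test_substrate_order_and_subset_are_free(self, diauxic_fixture):
        model, _, b0 = diauxic_fixture
        a = validate_setup(model, {"o2": -1.0, "glc": 5.0, "byp": 0.0}, b0)
        b = validate_setup(model, {"glc": 5.0, "byp": 0.0, "o2": -1.0}, b0)
        assert a.state.concentrations == b.state.concentrations

    def test_unlisted_exchange_defaults_to_excess(self, diauxic_fixture, caplog):
        model, _, b0 = diauxic_fixture
        with caplog.at_level("WARNING", logger="adfba.dynamics"):
            ctx = validate_setup(model, {"glc": 5.0}, b0)
        assert {"byp", "o2"} <= ctx.state.excess
        assert any("EXCESS" in r.message for r in caplog.records)

    def test_nonpositive_biomass_rejected(self, diauxic_fixture):
        model, conc, _ = diauxic_fixture
        with pytest.raises(ConfigurationError, match="biomass"):
            validate_setup(model, conc, 0.0)

    def test_unknown_metabolite_rejected(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        with pytest.raises(ConfigurationError, match="nope"):
            validate_setup(model, {**conc, "nope": 1.0}, b0)

    def test_bad_schedule_column_rejected(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        sched = pd.DataFrame({"EX_glc[mid]": [1.0]}, index=[0.0])
        with pytest.raises(ScheduleError, match=r"\[low\]"):
            validate_setup(model, conc, b0, InterventionSet(bounds_schedule=sched))


class TestInterpolateSchedule:
    def test_linear_midpoint(self):
        sched = pd.DataFrame({"EX_glc[low]": [-10.0, -4.0]}, index=[0.0, 12.0])
        dense = interpolate_schedule(sched, np.array([6.0]))
        assert dense.loc[6.0, "EX_glc[low]"] == pytest.approx(-7.0, abs=1e-12)

    def test_knot_values_exact(self):
        sched = pd.DataFrame({"R[upp]": [3.0, 9.0, 1.0]}, index=[0.0, 4.0, 24.0])
        dense = interpolate_schedule(sched, np.array([0.0, 4.0, 24.0]))
        assert list(dense["R[upp]"]) == [3.0, 9.0, 1.0]

    def test_inner_knot_changes_slope(self):
        # a 4 h knot splits [0, 12] into two phases with distinct slopes
        sched = pd.DataFrame({"R[low]": [-10.0, -8.0, -1.0]}, index=[0.0, 4.0, 12.0])
        grid = np.array([2.0, 8.0])
        dense = interpolate_schedule(sched, grid)
        slope_early = (dense.loc[2.0].item() - (-10.0)) / 2.0
        slope_late = (dense.loc[8.0].item() - (-8.0)) / 4.0
        assert slope_early == pytest.approx(0.5)
        assert slope_late == pytest.approx(7.0 / 8.0)
        assert slope_early != slope_late

    def test_no_extrapolation(self):
        sched = pd.DataFrame({"R[low]": [-10.0, -4.0]}, index=[0.0, 12.0])
        with pytest.raises(ScheduleError, match="knot range"):
            interpolate_schedule(sched, np.array([13.0]))


class TestClampUptake:
    def test_availability_formula(self, diauxic_fixture):
        model, _, _ = diauxic_fixture
        ctx = validate_setup(model, {"glc": 0.5, "byp": 0.0, "o2": -1.0}, 1.0)
        bounds = clamp_uptake_bounds(ctx.state, ctx, dt=1.0)
        assert bounds["EX_glc"][0] == pytest.approx(-0.5)

    def test_never_below_current_limit(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        ctx = validate_setup(model, {"glc": 1e6, "byp": 0.0, "o2": -1.0}, b0)
        bounds = clamp_uptake_bounds(ctx.state, ctx, dt=1.0)
        assert bounds["EX_glc"][0] == -10.0  # plenty available: limit untouched

    def test_secretion_bound_untouched(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        ctx = validate_setup(model, conc, b0)
        bounds = clamp_uptake_bounds(ctx.state, ctx, dt=1.0)
        assert bounds["EX_byp"][1] == 1000.0


class TestClampProperties:
    """Clamp monotonicity over arbitrary pool/biomass/step combinations."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        conc=st.floats(0.0, 1e4),
        biomass=st.floats(1e-3, 10.0),
        dt=st.floats(1e-3, 4.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_clamped_bound_between_original_and_zero(self, conc, biomass, dt):
        from adfba import validate_setup
        from adfba.dynamics import clamp_uptake_bounds
        from adfba.fixtures import make_toy_model

        model, _, _ = make_toy_model("diauxic")
        ctx = validate_setup(model, {"glc": conc, "byp": 0.0, "o2": -1.0}, biomass)
        bounds = clamp_uptake_bounds(ctx.state, ctx, dt=dt)
        lb = bounds["EX_glc"][0]
        assert -10.0 <= lb <= 0.0
        assert lb >= max(-10.0, -conc / (biomass * dt)) - 1e-12


class TestUpdateState:
    def _ctx(self, diauxic_fixture, conc):
        model, _, _ = diauxic_fixture
        return validate_setup(model, conc, 0.1)

    def _solution(self, model, **fluxes):
        values = pd.Series(0.0, index=model.reaction_ids)
        for rid, v in fluxes.items():
            values[rid] = v
        return FluxSolution(values, float(values @ [r.objective_coefficient for r in model.reactions]), "optimal")

    def test_euler_limit_at_zero_growth(self, diauxic_fixture):
        ctx = self._ctx(diauxic_fixture, {"glc": 5.0, "byp": 0.0, "o2": -1.0})
        sol = self._solution(ctx.model, EX_glc=-10.0)
        update_state(ctx.state, ctx, sol, dt=1.0)
        assert ctx.state.concentrations["glc"] == pytest.approx(4.0, abs=1e-12)

    def test_exponential_consumption_integral(self, diauxic_fixture):
        model, _, _ = diauxic_fixture
        ctx = validate_setup(model, {"glc": 5.0, "byp": 0.0, "o2": -1.0}, 1.0)
        sol = self._solution(model, EX_glc=-1.0, Biomass=0.1)
        update_state(ctx.state, ctx, sol, dt=1.0)
        expected = 5.0 - (math.exp(0.1) - 1.0) / 0.1
        assert ctx.state.concentrations["glc"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(3.9483, abs=5e-5)

    def test_zero_exchange_grows_biomass_only(self, diauxic_fixture):
        model, _, _ = diauxic_fixture
        ctx = validate_setup(model, {"glc": 5.0, "byp": 0.0, "o2": -1.0}, 0.5)
        sol = self._solution(model, Biomass=0.2)
        update_state(ctx.state, ctx, sol, dt=1.0)
        assert ctx.state.concentrations["glc"] == 5.0
        assert ctx.state.biomass == pytest.approx(0.5 * math.exp(0.2), abs=1e-12)


class TestInterventions:
    def test_scheduled_addition_is_differential(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        sched = pd.DataFrame({"glc": [5.0]}, index=[2.0])
        ctx = validate_setup(
            model, conc, b0, InterventionSet(concentration_schedule=sched)
        )
        before = ctx.state.concentrations["glc"]
        apply_interventions(ctx.state, model, ctx.interventions, t=2.0, dt=1.0)
        assert ctx.state.concentrations["glc"] == pytest.approx(before + 5.0)

    def test_all_zero_schedule_is_neutral(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        grid = np.arange(0.0, 9.0)
        zeros = pd.DataFrame({"glc": np.zeros(len(grid))}, index=grid)
        plain = run_adaptive_dfba(model, conc, b0, t_end=8, dt=1.0)
        with_sched = run_adaptive_dfba(
            model, conc, b0, t_end=8, dt=1.0,
            interventions=InterventionSet(concentration_schedule=zeros),
        )
        assert np.array_equal(plain.biomass, with_sched.biomass)
        assert plain.concentrations.equals(with_sched.concentrations)

    def test_identity_callbacks_are_neutral(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        plain = run_adaptive_dfba(model, conc, b0, t_end=8, dt=1.0)
        iv = InterventionSet(
            bounds_callback=lambda m, c, f, dt: {},
            concentration_callback=lambda c: dict(c),
        )
        same = run_adaptive_dfba(model, conc, b0, t_end=8, dt=1.0, interventions=iv)
        assert np.array_equal(plain.biomass, same.biomass)
        assert plain.concentrations.equals(same.concentrations)
        assert np.array_equal(plain.fluxes.to_numpy(), same.fluxes.to_numpy())

    def test_fed_batch_callback_prevents_exhaustion(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture

        def feed(concentrations):
            out = dict(concentrations)
            if out["glc"] < 1.0:
                out["glc"] += 10.0
            return out

        control = run_adaptive_dfba(model, conc, b0, t_end=8, dt=0.5)
        fed = run_adaptive_dfba(
            model, conc, b0, t_end=8, dt=0.5,
            interventions=InterventionSet(concentration_callback=feed),
        )
        assert fed.concentrations["glc"].min() >= 0.0
        # control exhausts glucose; the fed culture keeps growing on it
        assert control.concentrations["glc"].iloc[-1] == pytest.approx(0.0, abs=1e-9)
        assert fed.biomass[-1] > control.biomass[-1]

    def test_malformed_bounds_callback_names_callback(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture

        def broken_callback(m, c, f, dt):
            return [1, 2, 3]

        with pytest.raises(ContractError, match="broken_callback"):
            run_adaptive_dfba(
                model, conc, b0, t_end=2, dt=1.0,
                interventions=InterventionSet(bounds_callback=broken_callback),
            )

    def test_missing_row_error_without_interpolation(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        sched = pd.DataFrame({"EX_glc[low]": [-10.0, -4.0]}, index=[0.0, 8.0])
        with pytest.raises(ScheduleError, match="no row"):
            run_adaptive_dfba(
                model, conc, b0, t_end=8, dt=1.0,
                interventions=InterventionSet(bounds_schedule=sched),
                interpolate_schedules=False,
            )

    def test_callback_can_convert_excess_to_tracked(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture

        def cap_oxygen(concentrations):
            out = dict(concentrations)
            if out["o2"] < 0:  # still the EXCESS sentinel
                out["o2"] = 2.0
            return out

        traj = run_adaptive_dfba(
            model, conc, b0, t_end=6, dt=0.5,
            interventions=InterventionSet(concentration_callback=cap_oxygen),
        )
        assert "o2" not in traj.excess_metabolites
        assert np.isfinite(traj.concentrations["o2"].iloc[-1])


class TestMainLoop:
    def test_diauxic_two_phase_growth(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        traj = run_adaptive_dfba(model, conc, b0, t_end=10, dt=0.25)
        assert traj.completed
        glc = traj.concentrations["glc"].to_numpy()
        byp = traj.concentrations["byp"].to_numpy()
        assert glc[-1] == pytest.approx(0.0, abs=1e-9)
        # by-product excreted then re-consumed: rises and comes back down
        assert byp.max() > 1.0 and byp[-1] < byp.max() / 2
        v = traj.fluxes["EX_byp"].to_numpy()
        signs = np.sign(v[np.abs(v) > 1e-9])
        assert int(np.sum(np.diff(signs) != 0)) == 1
        # two growth phases: distinct specific growth rates before/after switch
        mu = traj.fluxes["Biomass"].to_numpy()
        assert mu[0] == pytest.approx(0.8, abs=1e-6)
        assert 0.0 < mu[np.argmax(byp) + 2] < 0.5 * mu[0]

    def test_forced_secretion_terminates_early(self, secretion_fixture):
        model, conc, b0 = secretion_fixture
        free = run_adaptive_dfba(model, conc, b0, t_end=12, dt=0.5)
        sched = pd.DataFrame({"EX_prot[low]": [2.0, 2.0]}, index=[0.0, 12.0])
        forced = run_adaptive_dfba(
            model, conc, b0, t_end=12, dt=0.5,
            interventions=InterventionSet(bounds_schedule=sched),
        )
        assert free.completed
        assert not forced.completed
        assert forced.step_status[-1] == "infeasible"
        assert forced.times[-1] < free.times[-1]

    @pytest.mark.parametrize("kind,dt,t_end", [
        ("minimal-chain", 0.01, 0.05),
        ("diauxic", 0.25, 8.0),
    ])
    def test_matches_classic_dfba_oracle(self, kind, dt, t_end):
        """With no interventions the engine is classic SOA-DFBA, step for step."""
        from adfba.fixtures import make_toy_model
        from adfba.model_io import find_biomass_reaction

        model, conc, b0 = make_toy_model(kind)
        biomass_id, _ = find_biomass_reaction(model)
        tracked = {m: rid for m, rid in {
            "A": "EX_A", "glc": "EX_glc", "byp": "EX_byp",
        }.items() if rid in set(model.reaction_ids) and rid != biomass_id}
        conc_tracked = {m: v for m, v in conc.items() if m in tracked}

        traj = run_adaptive_dfba(model, conc, b0, t_end=t_end, dt=dt)
        times, biomass, concs = classic_dfba_oracle(
            model, conc_tracked, b0, t_end, dt, biomass_id, tracked
        )
        np.testing.assert_allclose(traj.times, times, atol=1e-12)
        np.testing.assert_allclose(traj.biomass, biomass, atol=1e-9)
        for met in tracked:
            np.testing.assert_allclose(
                traj.concentrations[met].to_numpy(), concs[met].to_numpy(),
                atol=1e-9,
            )

    def test_objective_decoupled_from_biomass(self, secretion_fixture):
        """Objective = secretion, biomass forced at its own rate: the biomass
        series must integrate the biomass-reaction flux, not the objective."""
        model, conc, b0 = secretion_fixture
        rxns = []
        for r in model.reactions:
            if r.id == "Biomass":
                r = replace(r, objective_coefficient=0.0, lower_bound=0.1)
            elif r.id == "EX_prot":
                r = replace(r, objective_coefficient=1.0)
            rxns.append(r)
        decoupled = MetabolicModel(model.metabolites, rxns, id="decoupled")
        traj = run_adaptive_dfba(
            decoupled, conc, b0, t_end=4, dt=0.5, biomass_reaction="Biomass"
        )
        assert traj.completed
        mu = traj.fluxes["Biomass"].to_numpy()
        np.testing.assert_allclose(mu[:-1], 0.1, atol=1e-9)
        secretion = traj.fluxes["EX_prot"].to_numpy()
        assert secretion[0] > 1.0  # the objective drives secretion, not growth
        expected = b0 * np.exp(0.1 * traj.times)
        np.testing.assert_allclose(traj.biomass, expected, rtol=1e-9)

    def test_step_refinement_converges(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        coarse = run_adaptive_dfba(model, conc, b0, t_end=2.0, dt=0.5)
        fine = run_adaptive_dfba(model, conc, b0, t_end=2.0, dt=0.25)
        assert coarse.biomass[-1] == pytest.approx(fine.biomass[-1], rel=0.02)

    def test_mtf_trajectory_practically_equivalent(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        fba = run_adaptive_dfba(model, conc, b0, t_end=8, dt=0.5, solver="fba")
        mtf = run_adaptive_dfba(model, conc, b0, t_end=8, dt=0.5, solver="mtf")
        np.testing.assert_allclose(fba.biomass, mtf.biomass, rtol=0.01)

    def test_per_step_fva_brackets_fluxes(self, diauxic_fixture):
        model, conc, b0 = diauxic_fixture
        traj = run_adaptive_dfba(model, conc, b0, t_end=2, dt=0.5, fva=0.9)
        assert traj.fva_min is not None
        for rid in model.reaction_ids:
            assert np.all(
                traj.fva_min[rid].to_numpy() - 1e-6
                <= traj.fluxes[rid].to_numpy()[: len(traj.fva_min)]
            )
            assert np.all(
                traj.fluxes[rid].to_numpy()[: len(traj.fva_max)]
                <= traj.fva_max[rid].to_numpy() + 1e-6
            )

    def test_resource_safety_randomised(self):
        from adfba.fixtures import make_random_scenario

        for seed in range(10):
            kind, (model, conc, b0), dt, t_end = make_random_scenario(seed)
            traj = run_adaptive_dfba(model, conc, b0, t_end=t_end, dt=dt)
            tracked = [c for c in traj.concentrations.columns
                       if c not in traj.excess_metabolites]
            assert traj.concentrations[tracked].min().min() >= -1e-9

    def test_deterministic_output(self, diauxic_fixture, tmp_path):
        model, conc, b0 = diauxic_fixture
        paths = []
        for i in (0, 1):
            traj = run_adaptive_dfba(model, conc, b0, t_end=6, dt=0.5)
            p = tmp_path / f"t{i}.tsv"
            write_trajectory(traj, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
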