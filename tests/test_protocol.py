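import numpy as np
import pandas as pd
import pytest

from heatbalance import calorimetry as cal
from heatbalance.benchmarks import reference_conditions
from heatbalance.protocol import (
    EVALUATION_WINDOW_MIN,
    NoInflectionError,
    RampSchedule,
    build_ramp,
    critical_limit,
    detect_inflection,
)
from heatbalance.synthetic import simulate_trial


def brute_force_breakpoint(t, y, slope_threshold=0.1, grid=1.0, margin=5.0):
    """Independent oracle: exhaustive grid search with an explicitly
    parameterised continuous two-segment model (value at the break plus the
    two segment slopes), solved by normal equations."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    candidates = np.arange(np.ceil((t[0] + margin) / grid) * grid, t[-1] - margin + 1e-9, grid)
    best = None
    for b in candidates:
        if (t < b).sum() < 2 or (t >= b).sum() < 2:
            continue
        dt = t - b
        X = np.column_stack([np.ones_like(t), np.minimum(dt, 0.0), np.maximum(dt, 0.0)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        sse = float(np.sum((y - X @ beta) ** 2))
        s_pre, s_post = beta[1] * 60.0, beta[2] * 60.0
        if s_post - s_pre < slope_threshold or s_post <= 0:
            continue
        if best is None or sse < best[0] - 1e-12:
            best = (sse, b, s_pre, s_post)
    return best


def flat_then_rising(t, break_min, post_slope_c_per_h, baseline=37.0):
    t = np.asarray(t, float)
    return baseline + np.where(t >= break_min, post_slope_c_per_h / 60.0 * (t - break_min), 0.0)


class TestBuildRamp:
    def test_humidity_ramp_step_count(self):
        sched = RampSchedule(mode="P_crit", held_value=36.0, start_value=20.0)
        trace = build_ramp(sched, 60.0)
        assert trace["t_db_c"].nunique() == 1
        assert trace["p_a_mmhg"].iloc[0] == 20.0
        assert trace["p_a_mmhg"].iloc[-1] == 26.0  # 6 five-minute steps after 30-min hold
        assert sched.steps_completed(59.0) == 6

    def test_temperature_ramp_final_value(self):
        sched = RampSchedule(mode="T_crit", held_value=12.0, start_value=40.0)
        trace = build_ramp(sched, 90.0)
        assert trace["p_a_mmhg"].nunique() == 1
        assert trace["t_db_c"].iloc[-1] == 52.0

    def test_no_steps_gives_constant_trace(self):
        sched = RampSchedule(mode="P_crit", held_value=36.0, start_value=20.0)
        trace = build_ramp(sched, 30.0)
        assert trace["p_a_mmhg"].nunique() == 1

    def test_saturating_ramp_truncated_with_warning(self):
        sched = RampSchedule(mode="P_crit", held_value=30.0, start_value=28.0)
        with pytest.warns(UserWarning, match="saturation"):
            trace = build_ramp(sched, 120.0)
        from heatbalance.psychro import saturation_vapor_pressure

        assert trace["p_a_mmhg"].max() <= saturation_vapor_pressure(30.0) + 1e-9

    def test_piecewise_constant_between_boundaries(self):
        sched = RampSchedule(mode="P_crit", held_value=36.0, start_value=20.0)
        trace = build_ramp(sched, 60.0, sample_interval=0.5)
        within = trace[(trace.time_min >= 35.0) & (trace.time_min < 40.0)]
        assert within["p_a_mmhg"].nunique() == 1


class TestDetectInflection:
    def test_noiseless_breakpoint_recovered_exactly(self):
        t = np.arange(30.0, 121.0, 1.0)
        r = detect_inflection(t, flat_then_rising(t, 70.0, 0.6))
        assert r.inflection_time == 70.0
        assert r.pre_slope == pytest.approx(0.0, abs=1e-9)
        assert r.post_slope == pytest.approx(0.6, abs=1e-9)

    def test_constant_series_has_no_inflection(self):
        t = np.arange(30.0, 121.0, 1.0)
        with pytest.raises(NoInflectionError):
            detect_inflection(t, np.full_like(t, 37.0))

    def test_cooling_series_has_no_inflection(self):
        t = np.arange(30.0, 121.0, 1.0)
        with pytest.raises(NoInflectionError):
            detect_inflection(t, 37.5 - 0.01 * (t - 30.0))

    def test_vertical_shift_invariance(self):
        t = np.arange(30.0, 121.0, 1.0)
        rng = np.random.default_rng(3)
        y = flat_then_rising(t, 75.0, 0.5) + rng.normal(0, 0.05, t.shape)
        a = detect_inflection(t, y)
        b = detect_inflection(t, y + 1.7)
        assert a.inflection_time == b.inflection_time
        assert a.pre_slope == pytest.approx(b.pre_slope)
        assert a.post_slope == pytest.approx(b.post_slope)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        t = np.arange(30.0, 111.0, 0.5)  # 161 points
        rng = np.random.default_rng(seed)
        y = flat_then_rising(t, 72.0, 0.5) + rng.normal(0, 0.05, t.shape)
        r = detect_inflection(t, y)
        sse, b, s_pre, s_post = brute_force_breakpoint(t, y)
        assert r.inflection_time == b
        assert r.sse == pytest.approx(sse, rel=1e-9)
        assert r.pre_slope == pytest.approx(s_pre, abs=1e-9)
        assert r.post_slope == pytest.approx(s_post, abs=1e-9)

    def test_short_series_rejected(self):
        t = np.arange(30.0, 50.0, 1.0)
        with pytest.raises(ValueError, match="30 min"):
            detect_inflection(t, np.full_like(t, 37.0))

    def test_gap_interpolated_with_warning(self):
        t = np.concatenate([np.arange(30.0, 60.0), np.arange(65.0, 121.0)])
        y = flat_then_rising(t, 80.0, 0.6)
        with pytest.warns(UserWarning, match="interpolated"):
            r = detect_inflection(t, y)
        assert r.inflection_time == pytest.approx(80.0, abs=1.0)


class TestCriticalLimit:
    def test_recovers_generator_environment(self, noiseless_trial):
        trial, gt = noiseless_trial
        cl = critical_limit(trial)
        assert cl.inflection_time == gt.inflection_time
        assert cl.critical_env.t_db == pytest.approx(gt.t_db)
        # critical vapor pressure within one ramp step of the generator's step
        assert abs(cl.critical_env.p_a - gt.p_a) <= trial.schedule.step_size
        assert cl.post_slope > cl.pre_slope

    def test_window_is_pre_inflection_only(self, noiseless_trial):
        trial, gt = noiseless_trial
        ref = critical_limit(trial)
        perturbed = trial.data.copy()
        late = perturbed["time_min"] >= gt.inflection_time + 1.0
        for col in ("t_chest_c", "t_arm_c", "t_thigh_c", "t_leg_c"):
            perturbed.loc[late, col] += 0.8
        trial2 = type(trial)(
            data=perturbed, subject=trial.subject, activity=trial.activity,
            schedule=trial.schedule, mass_pre_kg=trial.mass_pre_kg,
            mass_post_kg=trial.mass_post_kg, gas=trial.gas, trial_id=trial.trial_id,
        )
        out = critical_limit(trial2)
        assert out.inflection_time == ref.inflection_time
        assert out.balance.omega_max == pytest.approx(ref.balance.omega_max)
        assert out.skin.t_sk_bar == pytest.approx(ref.skin.t_sk_bar)

    def test_window_bounds(self, noiseless_trial):
        trial, gt = noiseless_trial
        cl = critical_limit(trial)
        win = trial.data[
            (trial.data.time_min >= cl.inflection_time - EVALUATION_WINDOW_MIN)
            & (trial.data.time_min < cl.inflection_time)
        ]
        assert win["p_a_mmhg"].nunique() == 1  # window sits inside one ramp step

    def test_compensable_trial_propagates_no_inflection(self, subject, humidity_ramp):
        from heatbalance.synthetic import TrueTrialParams, simulate_trial

        truth = TrueTrialParams(true_critical_step=10, noise_sd=0.0, skin_noise_sd=0.0)
        trial, _ = simulate_trial(subject, humidity_ramp, truth, rng=1)
        flat = trial.data.copy()
        flat["t_core_c"] = 37.0
        trial2 = type(trial)(
            data=flat, subject=trial.subject, activity=trial.activity,
            schedule=trial.schedule, mass_pre_kg=trial.mass_pre_kg,
            mass_post_kg=trial.mass_post_kg, gas=trial.gas,
        )
        with pytest.raises(NoInflectionError):
            critical_limit(trial2)

    def test_missing_gas_exchange_rejected(self, noiseless_trial):
        trial, _ = noiseless_trial
        trial2 = type(trial)(
            data=trial.data, subject=trial.subject, activity=trial.activity,
            schedule=trial.schedule, mass_pre_kg=trial.mass_pre_kg,
            mass_post_kg=trial.mass_post_kg, gas={5.0: list(trial.gas.values())[0]},
        )
        with pytest.raises(ValueError, match="gas"):
            critical_limit(trial2)


class TestGroupMeanLinearity:
    def test_dry_exchange_of_mean_temperatures_matches_reported_cells(self):
        """R+C is linear in temperatures, so the cell-mean fluxes should be
        reproducible from cell-mean temperatures; one reported cell carries a
        typographically inconsistent skin temperature and is tolerated."""
        ref = reference_conditions("young", "MinAct")
        recomputed = (ref["t_db"] - ref["t_sk_bar"]) / cal.I_T_DEFAULT
        within = (recomputed - ref["rc"]).abs() <= 1.0
        assert within.sum() >= 6
        assert not within.loc["40C"]  # the known inconsistent cell
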