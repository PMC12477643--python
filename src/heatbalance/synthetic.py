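"""Synthetic cohorts and ramp trials with known ground truth.

Real critical-limit experiments are expensive: hours per subject in an
environmental chamber. This module fabricates trials whose generating
parameters are known exactly, so the whole pipeline — ramp construction,
inflection detection, windowed heat balance, cohort statistics — can be
validated end to end. The generator reproduces the structural features the
analysis consumes and nothing more: a 30-min equilibration followed by unit
steps every 5 min, a flat-then-rising core temperature with a sharp known
breakpoint, skin temperatures that track dry-bulb temperature linearly and
saturate near 38.5 degC in extreme heat, gas exchange drawn around the
activity's target metabolic rate, and a body-mass loss exactly consistent
with a prescribed sweat rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import calorimetry as cal
from .protocol import RampSchedule, TrialTimeSeries, build_ramp
from .psychro import saturation_vapor_pressure

__all__ = [
    "CohortSpec",
    "TrueTrialParams",
    "TrialGroundTruth",
    "ACTIVITY_TARGET_W",
    "SKIN_SITE_OFFSETS",
    "generate_cohort",
    "draw_gas_exchange",
    "skin_temperature_model",
    "simulate_trial",
    "implied_ground_truth",
    "calibrated_start_value",
    "build_study",
    "first_uncompensable_step",
]

#: nominal whole-body metabolic rate (W) of each activity condition
ACTIVITY_TARGET_W = {"rest": 90.0, "MinAct": 150.0, "LightAmb": 250.0}

#: nominal whole-body sweat rate (g·m^-2·h^-1) by (age_group, activity)
DEFAULT_SWEAT_RATE = {
    ("older", "rest"): 65.0,
    ("older", "MinAct"): 90.0,
    ("young", "MinAct"): 150.0,
    ("young", "LightAmb"): 220.0,
}

#: fixed site offsets (degC) around the mean; weighted (0.3/0.3/0.2/0.2) sum is 0
SKIN_SITE_OFFSETS = {"chest": 0.5, "thigh": 0.1, "arm": -0.3, "leg": -0.6}

_AGE_RANGE = {"young": (18, 33), "older": (65, 92)}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling recipe for a synthetic subject cohort.

    Anthropometric defaults follow the study population this package is
    aimed at: unacclimated adults of average build (height 1.7 ± 0.1 m;
    mass 75 ± 15 kg young, 73 ± 17 kg older). Rest trials are performed
    only by older subjects and light ambulation only by young subjects;
    set ``allow_any_pairing`` to lift that design constraint.
    """

    n: int
    age_group: str = "young"
    activity: str = "MinAct"
    height_mean: float = 1.7
    height_sd: float = 0.1
    mass_mean: Optional[float] = None
    mass_sd: Optional[float] = None
    target_met_w: Optional[float] = None
    seed: int = 0
    allow_any_pairing: bool = False

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.age_group not in ("young", "older"):
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.activity not in ("rest", "MinAct", "LightAmb"):
            raise ValueError(f"unknown activity {self.activity!r}")
        if not self.allow_any_pairing:
            if self.activity == "rest" and self.age_group != "older":
                raise ValueError("rest trials are run only by older subjects")
            if self.activity == "LightAmb" and self.age_group != "young":
                raise ValueError("light ambulation is run only by young subjects")
        if self.mass_mean is None:
            object.__setattr__(
                self, "mass_mean", 75.0 if self.age_group == "young" else 73.0
            )
        if self.mass_sd is None:
            object.__setattr__(
                self, "mass_sd", 15.0 if self.age_group == "young" else 17.0
            )
        if self.target_met_w is None:
            object.__setattr__(self, "target_met_w", ACTIVITY_TARGET_W[self.activity])


@dataclass(frozen=True)
class TrueTrialParams:
    """Generating parameters of one synthetic trial.

    ``true_critical_step`` is the index k of the last compensable ramp step:
    core temperature is flat (slope ``pre_slope``) until the onset of step
    k+1 and rises at ``post_slope`` afterwards. Noise defaults (core 0.05,
    skin 0.15 degC; VO2 CV 5%) reflect telemetry-capsule and thermocouple
    precision; ``sample_interval_min`` defaults to the 15-s epoch at which
    ingestible telemetry capsules record.
    """

    true_critical_step: int
    baseline_tc: float = 37.0
    pre_slope: float = 0.0  # degC/h
    post_slope: float = 0.6  # degC/h
    noise_sd: float = 0.05  # degC, core temperature
    skin_noise_sd: float = 0.15  # degC, each site
    vo2_cv: float = 0.05
    sweat_rate: Optional[float] = None  # g·m^-2·h^-1
    post_minutes: float = 30.0
    sample_interval_min: float = 0.25
    skin_intercept: float = 30.8
    skin_slope: float = 0.155
    skin_cap: float = 38.5

    def __post_init__(self) -> None:
        if self.true_critical_step < 1:
            raise ValueError("true_critical_step must be >= 1")
        if self.post_slope <= 0:
            raise ValueError("post_slope must be positive")
        if self.noise_sd < 0 or self.skin_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class TrialGroundTruth:
    """Noise-free quantities implied by the generating parameters."""

    params: TrueTrialParams
    inflection_time: float
    t_db: float
    p_a: float
    t_sk_bar: float
    m_net: float
    rc: float
    e_req: float
    e_max: float
    omega: float


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0.0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated-normal rejection sampling failed")


def generate_cohort(spec: CohortSpec) -> list[cal.SubjectProfile]:
    """Draw a reproducible cohort of subject profiles from a spec."""
    rng = np.random.default_rng(spec.seed)
    lo_age, hi_age = _AGE_RANGE[spec.age_group]
    subjects = []
    for i in range(spec.n):
        height = _truncated_normal(rng, spec.height_mean, spec.height_sd, 1.4, 2.1)
        mass = _truncated_normal(rng, spec.mass_mean, spec.mass_sd, 40.0, 140.0)
        age = float(rng.integers(lo_age, hi_age + 1))
        sex = "F" if rng.random() < 0.5 else "M"
        subjects.append(
            cal.SubjectProfile(
                height_m=height,
                mass_kg=mass,
                age=age,
                sex=sex,
                subject_id=f"{spec.age_group[0].upper()}{i + 1:03d}",
            )
        )
    return subjects


def skin_temperature_model(
    t_db: float,
    intercept: float = 30.8,
    slope: float = 0.155,
    cap: float = 38.5,
) -> float:
    """Mean skin temperature as a function of dry-bulb temperature.

    Linear rise with ambient temperature, capped near 38.5 degC where
    vasodilation and sweating pin the skin in extreme heat. These are
    generator coefficients, not a physiological model; they place skin
    temperatures in the observed 35.5–38.5 degC band across 34–50 degC
    environments.
    """
    return min(intercept + slope * t_db, cap)


def draw_gas_exchange(
    rng: np.random.Generator,
    target_met_w: float,
    a_d: float,
    vo2_cv: float = 0.05,
    times: Sequence[float] = (5.0, 60.0),
) -> dict[float, cal.GasExchange]:
    """Two spirometry readings scattered around a target metabolic rate."""
    readings: dict[float, cal.GasExchange] = {}
    for t in times:
        rer = float(np.clip(rng.normal(0.84, 0.02), 0.75, 0.95))
        vo2_nominal = target_met_w * 60.0 / (cal.oxygen_energy_equivalent(rer) * 1000.0)
        vo2 = vo2_nominal * (1.0 + vo2_cv * rng.standard_normal())
        readings[float(t)] = cal.GasExchange(vo2=max(vo2, 0.05), rer=rer)
    return readings


def _mean_gas(gas: dict[float, cal.GasExchange]) -> cal.GasExchange:
    vals = list(gas.values())
    return cal.GasExchange(
        vo2=float(np.mean([g.vo2 for g in vals])),
        rer=float(np.mean([g.rer for g in vals])),
    )


def implied_ground_truth(
    subject: cal.SubjectProfile,
    schedule: RampSchedule,
    truth: TrueTrialParams,
    gas: dict[float, cal.GasExchange],
    activity: str,
    *,
    i_t: float = cal.I_T_DEFAULT,
    r_et: float = cal.R_ET_DEFAULT,
) -> TrialGroundTruth:
    """Noise-free heat balance at the true critical step.

    This is the closed-form value the analysis pipeline should recover:
    environment of ramp step k, model skin temperature, mean of the two
    gas-exchange draws, and the flux arithmetic applied to those.
    """
    k = truth.true_critical_step
    t_star = schedule.step_onset_time(k + 1)
    mid_of_step_k = schedule.step_onset_time(k) + schedule.step_minutes / 2.0
    t_db, p_a = schedule.environment_at(mid_of_step_k)
    t_sk = skin_temperature_model(
        t_db, truth.skin_intercept, truth.skin_slope, truth.skin_cap
    )
    gm = _mean_gas(gas)
    m = cal.metabolic_rate(gm, subject.a_d)
    if activity == "LightAmb":
        from .protocol import LIGHTAMB_GRADE, LIGHTAMB_SPEED_MS

        w = cal.external_work(subject.mass_kg, LIGHTAMB_SPEED_MS, LIGHTAMB_GRADE, subject.a_d)
    else:
        w = 0.0
    m_net = m - w
    rc = cal.dry_heat_exchange(t_db, t_sk, i_t)
    e_max, _ = cal.evaporative_capacity(t_sk, p_a, r_et)
    e_req = cal.required_evaporation(m_net, rc)
    omega = cal.max_skin_wettedness(e_req, e_max)
    return TrialGroundTruth(
        params=truth, inflection_time=t_star, t_db=t_db, p_a=p_a, t_sk_bar=t_sk,
        m_net=m_net, rc=rc, e_req=e_req, e_max=e_max, omega=omega,
    )


def simulate_trial(
    subject: cal.SubjectProfile,
    schedule: RampSchedule,
    truth: TrueTrialParams,
    rng: np.random.Generator | int | None = None,
    activity: str = "MinAct",
    gas: Optional[dict[float, cal.GasExchange]] = None,
    spec: Optional[CohortSpec] = None,
) -> tuple[TrialTimeSeries, TrialGroundTruth]:
    """Fabricate one ramp trial with a known critical step.

    Core temperature is ``baseline + pre_slope·t`` plus Gaussian noise up to
    the onset of step k+1 (k the true critical step), then kinks upward at
    ``post_slope``. Skin sites follow :func:`skin_temperature_model` of the
    scheduled dry-bulb with fixed site offsets and independent noise. Body
    mass loss equals the prescribed sweat rate times surface area times
    duration, so the analysis recovers that sweat rate within rounding.

    Returns the trial and the noise-free ground truth it was built from.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = truth.true_critical_step
    t_star = schedule.step_onset_time(k + 1)
    total = t_star + truth.post_minutes
    if total <= schedule.equilibration_minutes:
        raise ValueError("true critical step lies before the ramp starts")

    env = build_ramp(
        schedule, total + truth.sample_interval_min / 2.0,
        sample_interval=truth.sample_interval_min,
    )
    time = env["time_min"].to_numpy()
    pre = truth.pre_slope / 60.0
    post = truth.post_slope / 60.0
    tc_clean = truth.baseline_tc + pre * time
    after = time >= t_star
    tc_clean = tc_clean + np.where(after, post * (time - t_star), 0.0)
    t_c = tc_clean + rng.normal(0.0, truth.noise_sd, size=time.shape)

    t_sk_mean = np.array(
        [
            skin_temperature_model(td, truth.skin_intercept, truth.skin_slope, truth.skin_cap)
            for td in env["t_db_c"]
        ]
    )
    sites = {}
    for site, off in SKIN_SITE_OFFSETS.items():
        sites[f"t_{site}_c"] = (
            t_sk_mean + off + rng.normal(0.0, truth.skin_noise_sd, size=time.shape)
        )

    if gas is None:
        spec_target = spec.target_met_w if spec is not None else ACTIVITY_TARGET_W[activity]
        gas = draw_gas_exchange(rng, spec_target, subject.a_d, truth.vo2_cv)

    sr = truth.sweat_rate
    if sr is None:
        age_group = "young" if subject.age < 50 else "older"
        sr = DEFAULT_SWEAT_RATE.get((age_group, activity), 100.0)
        truth = replace(truth, sweat_rate=sr)
    duration_h = (time[-1] - time[0]) / 60.0
    mass_loss = sr * subject.a_d * duration_h / 1000.0
    mass_pre = subject.mass_kg
    mass_post = mass_pre - mass_loss

    data = pd.DataFrame(
        {
            "time_min": time,
            "t_core_c": t_c,
            "t_chest_c": sites["t_chest_c"],
            "t_arm_c": sites["t_arm_c"],
            "t_thigh_c": sites["t_thigh_c"],
            "t_leg_c": sites["t_leg_c"],
            "t_db_c": env["t_db_c"].to_numpy(),
            "p_a_mmhg": env["p_a_mmhg"].to_numpy(),
        }
    )
    trial = TrialTimeSeries(
        data=data,
        subject=subject,
        activity=activity,
        schedule=schedule,
        mass_pre_kg=mass_pre,
        mass_post_kg=mass_post,
        gas=gas,
        trial_id=f"{subject.subject_id}-{schedule.mode}-{schedule.held_value:g}",
    )
    gt = implied_ground_truth(subject, schedule, truth, gas, activity)
    return trial, gt


def calibrated_start_value(
    subject: cal.SubjectProfile,
    *,
    held_t_db: float,
    critical_step: int,
    target_omega: float,
    gas: dict[float, cal.GasExchange],
    activity: str = "MinAct",
    truth: Optional[TrueTrialParams] = None,
    step_size: float = 1.0,
    i_t: float = cal.I_T_DEFAULT,
    r_et: float = cal.R_ET_DEFAULT,
) -> float:
    """Ramp start vapor pressure placing a target wettedness at step k.

    For a humidity-ramp trial the skin saturation pressure and the dry and
    metabolic terms are fixed by the held dry-bulb, so the ambient vapor
    pressure at which E_req/E_max equals ``target_omega`` has the closed
    form p_a* = P_s,sk - R_e,t · E_req / omega. The returned start value
    puts p_a* exactly at ramp step ``critical_step``.
    """
    truth = truth or TrueTrialParams(true_critical_step=critical_step)
    t_sk = skin_temperature_model(
        held_t_db, truth.skin_intercept, truth.skin_slope, truth.skin_cap
    )
    gm = _mean_gas(gas)
    m = cal.metabolic_rate(gm, subject.a_d)
    if activity == "LightAmb":
        from .protocol import LIGHTAMB_GRADE, LIGHTAMB_SPEED_MS

        m -= cal.external_work(subject.mass_kg, LIGHTAMB_SPEED_MS, LIGHTAMB_GRADE, subject.a_d)
    rc = cal.dry_heat_exchange(held_t_db, t_sk, i_t)
    e_req = cal.required_evaporation(m, rc)
    p_s_sk = saturation_vapor_pressure(t_sk)
    p_a_star = p_s_sk - r_et * e_req / target_omega
    if p_a_star <= 0:
        raise ValueError("target wettedness unreachable: implied vapor pressure <= 0")
    return p_a_star - critical_step * step_size


def build_study(
    spec: CohortSpec,
    *,
    target_omega: float = 0.55,
    held_t_db: float = 38.0,
    critical_step: int = 10,
    truth_template: Optional[TrueTrialParams] = None,
) -> list[tuple[TrialTimeSeries, TrialGroundTruth]]:
    """A cohort of humidity-ramp trials with a common true wettedness.

    Each subject's gas exchange is drawn first; the ramp start value is then
    calibrated so the noise-free wettedness at the true critical step equals
    ``target_omega`` exactly for that subject. One master seed drives every
    stochastic draw.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = generate_cohort(replace(spec, seed=int(rng.integers(2**31))))
    template = truth_template or TrueTrialParams(true_critical_step=critical_step)
    template = replace(template, true_critical_step=critical_step)
    out = []
    for subject in subjects:
        gas = draw_gas_exchange(rng, spec.target_met_w, subject.a_d, template.vo2_cv)
        start = calibrated_start_value(
            subject,
            held_t_db=held_t_db,
            critical_step=critical_step,
            target_omega=target_omega,
            gas=gas,
            activity=spec.activity,
            truth=template,
        )
        schedule = RampSchedule(mode="P_crit", held_value=held_t_db, start_value=start)
        trial, gt = simulate_trial(
            subject, schedule, template, rng, activity=spec.activity, gas=gas, spec=spec
        )
        out.append((trial, gt))
    return out


def first_uncompensable_step(schedule: RampSchedule, t_sk_bar: float) -> Optional[int]:
    """First ramp step whose vapor pressure reaches skin saturation.

    Only meaningful for humidity ramps; returns None if the dry limit is
    never reached (including all temperature ramps at fixed vapor pressure).
    """
    if schedule.mode != "P_crit":
        return None
    p_s_sk = saturation_vapor_pressure(t_sk_bar)
    if schedule.start_value >= p_s_sk:
        return 0
    k = int(np.ceil((p_s_sk - schedule.start_value) / schedule.step_size))
    return k
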