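"""Ramp-trial protocol: environment schedule, core-temperature inflection,
and the heat balance at the critical environmental limit.

A trial holds one environmental variable fixed and ramps the other in unit
steps every five minutes after a 30-minute equilibration: ``P_crit`` trials
hold dry-bulb temperature and ramp vapor pressure, ``T_crit`` trials the
reverse. While the environment is compensable, core temperature is stable;
once evaporative capacity can no longer absorb the required heat loss, core
temperature turns upward. The breakpoint of a continuous two-segment linear
fit to the core-temperature trace marks that upper limit of compensable
heat stress, and the heat balance is evaluated over the five minutes
immediately preceding it — the final compensable condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import calorimetry as cal
from .psychro import EnvironmentState, saturation_vapor_pressure

__all__ = [
    "RampSchedule",
    "TrialTimeSeries",
    "InflectionResult",
    "CriticalLimit",
    "NoInflectionError",
    "build_ramp",
    "detect_inflection",
    "critical_limit",
    "SLOPE_INCREASE_THRESHOLD",
    "EVALUATION_WINDOW_MIN",
]

log = logging.getLogger(__name__)

#: minimum slope increase (degC/h) for an admissible breakpoint
SLOPE_INCREASE_THRESHOLD = 0.1
#: width of the pre-inflection evaluation window (min)
EVALUATION_WINDOW_MIN = 5.0

#: canonical per-sample column order of the trial time-series table
TRIAL_COLUMNS = [
    "time_min",
    "t_core_c",
    "t_chest_c",
    "t_arm_c",
    "t_thigh_c",
    "t_leg_c",
    "t_db_c",
    "p_a_mmhg",
]

#: treadmill parameters of the light-ambulation condition (2.2 mi/h, 3% grade)
LIGHTAMB_SPEED_MS = 2.2 * cal.MPH_TO_MS
LIGHTAMB_GRADE = 0.03


class NoInflectionError(RuntimeError):
    """No admissible upward core-temperature breakpoint: trial compensable throughout."""


@dataclass(frozen=True)
class RampSchedule:
    """Stepwise chamber schedule for one trial.

    ``mode`` selects which variable ramps: ``"P_crit"`` holds ``held_value``
    (dry-bulb, degC) and ramps vapor pressure from ``start_value`` in
    ``step_size`` mmHg increments; ``"T_crit"`` holds vapor pressure (mmHg)
    and ramps dry-bulb. Steps occur every ``step_minutes`` starting at the
    end of equilibration.
    """

    mode: str
    held_value: float
    start_value: float
    step_size: float = 1.0
    step_minutes: float = 5.0
    equilibration_minutes: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in ("P_crit", "T_crit"):
            raise ValueError(f"mode must be 'P_crit' or 'T_crit', got {self.mode!r}")
        if self.step_size <= 0 or self.step_minutes <= 0:
            raise ValueError("step_size and step_minutes must be positive")
        if self.equilibration_minutes < 0:
            raise ValueError("equilibration must be non-negative")

    def steps_completed(self, t: float) -> int:
        """Number of ramp increments applied by time ``t`` (min)."""
        if t < self.equilibration_minutes:
            return 0
        return int(np.floor((t - self.equilibration_minutes) / self.step_minutes)) + 1

    def ramped_value(self, t: float) -> float:
        return self.start_value + self.step_size * self.steps_completed(t)

    def step_onset_time(self, k: int) -> float:
        """Trial time (min) at which ramp step ``k`` begins (k=0: equilibration value)."""
        if k <= 0:
            return 0.0
        return self.equilibration_minutes + (k - 1) * self.step_minutes

    def environment_at(self, t: float) -> tuple[float, float]:
        """(t_db, p_a) of the scheduled environment at trial time ``t``."""
        v = self.ramped_value(t)
        if self.mode == "P_crit":
            return self.held_value, v
        return v, self.held_value


def build_ramp(
    schedule: RampSchedule,
    total_minutes: float,
    sample_interval: float = 1.0,
) -> pd.DataFrame:
    """Piecewise-constant environment trace for a schedule.

    Returns a frame with ``time_min``, ``t_db_c`` and ``p_a_mmhg`` sampled
    every ``sample_interval`` minutes. A P_crit ramp that would exceed
    saturation at the held dry-bulb is truncated at saturation with a
    warning (the chamber cannot supersaturate).
    """
    if total_minutes < schedule.equilibration_minutes:
        raise ValueError("total_minutes must cover the equilibration period")
    time = np.arange(0.0, total_minutes, sample_interval)
    t_db = np.empty_like(time)
    p_a = np.empty_like(time)
    for i, t in enumerate(time):
        t_db[i], p_a[i] = schedule.environment_at(t)
    p_sat = np.array([saturation_vapor_pressure(td) for td in t_db])
    if np.any(p_a > p_sat):
        log.warning("ramp exceeds saturation; vapor pressure truncated at p_sat(t_db)")
        warnings.warn("ramp reaches saturation; p_a truncated", stacklevel=2)
        p_a = np.minimum(p_a, p_sat)
    return pd.DataFrame({"time_min": time, "t_db_c": t_db, "p_a_mmhg": p_a})


@dataclass
class TrialTimeSeries:
    """Synchronised records of one ramp trial plus its scalar metadata.

    ``data`` carries one row per sample with the columns in
    :data:`TRIAL_COLUMNS`. Gas exchange is measured twice (nominally at 5
    and 60 min); ``gas`` maps measurement time to the reading.
    """

    data: pd.DataFrame
    subject: cal.SubjectProfile
    activity: str
    schedule: RampSchedule
    mass_pre_kg: float
    mass_post_kg: float
    gas: dict[float, cal.GasExchange]
    treadmill_speed_ms: Optional[float] = None
    treadmill_grade: Optional[float] = None
    trial_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trial data missing columns: {missing}")
        t = self.data["time_min"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time_min must be strictly increasing")
        if self.activity not in ("rest", "MinAct", "LightAmb"):
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.activity == "LightAmb":
            if self.treadmill_speed_ms is None:
                self.treadmill_speed_ms = LIGHTAMB_SPEED_MS
            if self.treadmill_grade is None:
                self.treadmill_grade = LIGHTAMB_GRADE

    @property
    def duration_min(self) -> float:
        t = self.data["time_min"].to_numpy()
        return float(t[-1] - t[0])


@dataclass(frozen=True)
class InflectionResult:
    """Breakpoint of the two-segment core-temperature fit."""

    inflection_time: float
    pre_slope: float  # degC/h
    post_slope: float  # degC/h
    sse: float


@dataclass(frozen=True)
class CriticalLimit:
    """Critical environmental limit of one trial and the heat balance there."""

    inflection_time: float
    pre_slope: float
    post_slope: float
    critical_env: EnvironmentState
    skin: cal.SkinTemperatures
    balance: cal.HeatBalanceResult
    sweat: cal.SweatSummary


def _two_segment_fit(
    t: np.ndarray, y: np.ndarray, b: float
) -> tuple[float, float, float]:
    """Continuous two-segment least-squares fit with breakpoint ``b``.

    Returns (sse, pre_slope, post_slope) with slopes per minute.
    """
    hinge = np.maximum(t - b, 0.0)
    X = np.column_stack([np.ones_like(t), t, hinge])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), float(coef[1]), float(coef[1] + coef[2])


def _regularize_sampling(t: np.ndarray, y_cols: dict[str, np.ndarray]):
    """Interpolate onto a 1-min grid when gaps exceed 2 min."""
    if len(t) > 1 and np.max(np.diff(t)) > 2.0:
        log.warning("sampling gap > 2 min; linearly interpolating onto 1-min grid")
        warnings.warn("sampling gap > 2 min; interpolated", stacklevel=3)
        grid = np.arange(t[0], t[-1] + 1e-9, 1.0)
        y_cols = {k: np.interp(grid, t, v) for k, v in y_cols.items()}
        t = grid
    return t, y_cols


def detect_inflection(
    time_min: Sequence[float],
    t_core: Sequence[float],
    *,
    slope_threshold: float = SLOPE_INCREASE_THRESHOLD,
    grid_resolution: float = 1.0,
    min_segment_min: float = 5.0,
) -> InflectionResult:
    """Locate the upward core-temperature inflection of a ramp trial.

    Fits a continuous two-segment line for every candidate breakpoint on a
    1-minute grid and keeps the admissible breakpoint with minimal residual
    sum of squares. Admissibility demands an upward kink: the slope
    increase must be at least ``slope_threshold`` (degC/h) and the
    post-breakpoint slope positive. Ties go to the earliest breakpoint,
    which yields the more conservative (lower) critical environment.

    Parameters
    ----------
    time_min, t_core
        Trial time (minutes, strictly increasing, equilibration already
        excluded) and core temperature (degC). At least 30 minutes of data
        are required.
    slope_threshold
        Minimum post-minus-pre slope difference (degC/h).
    grid_resolution
        Spacing of candidate breakpoints (min).
    min_segment_min
        Candidates leave at least this much data (and two samples) on each
        side, so both segment slopes are identified.

    Raises
    ------
    NoInflectionError
        If no candidate satisfies the admissibility constraints — the trial
        never left the compensable zone.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(t_core, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("time and core-temperature arrays must be 1-D, equal length")
    if len(t) < 5:
        raise ValueError("too few samples for a two-segment fit")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time must be strictly increasing")
    if t[-1] - t[0] < 30.0:
        raise ValueError("need at least 30 min of data to fit the inflection")
    t, cols = _regularize_sampling(t, {"y": y})
    y = cols["y"]

    lo = t[0] + min_segment_min
    hi = t[-1] - min_segment_min
    start = np.ceil(lo / grid_resolution) * grid_resolution
    candidates = np.arange(start, hi + 1e-9, grid_resolution)
    thresh_per_min = slope_threshold / 60.0

    best: Optional[tuple[float, float, float, float]] = None
    for b in candidates:
        if np.sum(t < b) < 2 or np.sum(t >= b) < 2:
            continue
        sse, s_pre, s_post = _two_segment_fit(t, y, b)
        if s_post - s_pre < thresh_per_min or s_post <= 0.0:
            continue
        if best is None or sse < best[0]:
            best = (sse, b, s_pre, s_post)
    if best is None:
        raise NoInflectionError(
            "no admissible breakpoint: core temperature shows no upward inflection"
        )
    sse, b, s_pre, s_post = best
    return InflectionResult(
        inflection_time=float(b),
        pre_slope=s_pre * 60.0,
        post_slope=s_post * 60.0,
        sse=sse,
    )


def critical_limit(
    trial: TrialTimeSeries,
    *,
    i_t: float = cal.I_T_DEFAULT,
    r_et: float = cal.R_ET_DEFAULT,
    c_res: float = 0.0,
    e_res: float = 0.0,
    s: float = 0.0,
    slope_threshold: float = SLOPE_INCREASE_THRESHOLD,
) -> CriticalLimit:
    """Critical environmental limit of a trial and the heat balance there.

    Detects the core-temperature inflection on the post-equilibration trace,
    averages environment and skin temperatures over the five minutes
    immediately preceding it (the final compensable condition, half-open
    window ``[t*-5, t*)``), averages the trial's two gas-exchange readings,
    and assembles the full flux decomposition including maximal skin
    wettedness.
    """
    if len(trial.gas) < 2:
        raise ValueError("trial needs the two gas-exchange measurements")
    df = trial.data
    post = df[df["time_min"] >= trial.schedule.equilibration_minutes]
    infl = detect_inflection(
        post["time_min"].to_numpy(),
        post["t_core_c"].to_numpy(),
        slope_threshold=slope_threshold,
    )
    t_star = infl.inflection_time
    win = df[
        (df["time_min"] >= t_star - EVALUATION_WINDOW_MIN) & (df["time_min"] < t_star)
    ]
    if win.empty:
        raise ValueError("no samples in the pre-inflection evaluation window")

    skin = cal.SkinTemperatures(
        t_chest=float(win["t_chest_c"].mean()),
        t_arm=float(win["t_arm_c"].mean()),
        t_thigh=float(win["t_thigh_c"].mean()),
        t_leg=float(win["t_leg_c"].mean()),
    )
    env = EnvironmentState(
        t_db=float(win["t_db_c"].mean()), p_a=float(win["p_a_mmhg"].mean())
    )

    readings = list(trial.gas.values())
    gas_mean = cal.GasExchange(
        vo2=float(np.mean([g.vo2 for g in readings])),
        rer=float(np.mean([g.rer for g in readings])),
    )
    a_d = trial.subject.a_d
    m = cal.metabolic_rate(gas_mean, a_d)
    if trial.activity == "LightAmb":
        w_ext = cal.external_work(
            trial.subject.mass_kg, trial.treadmill_speed_ms, trial.treadmill_grade, a_d
        )
    else:
        w_ext = 0.0
    m_net = m - w_ext
    rc = cal.dry_heat_exchange(env.t_db, skin.t_sk_bar, i_t)
    e_max, p_s_sk = cal.evaporative_capacity(skin.t_sk_bar, env.p_a, r_et)
    e_req = cal.required_evaporation(m_net, rc, c_res, e_res, s)
    omega = cal.max_skin_wettedness(e_req, e_max)
    balance = cal.HeatBalanceResult(
        m=m, w_ext=w_ext, m_net=m_net, rc=rc, e_max=e_max, e_req=e_req,
        omega_max=omega, p_s_sk=p_s_sk, c_res=c_res, e_res=e_res, s=s,
    )
    sweat = cal.sweat_rate(
        trial.mass_pre_kg, trial.mass_post_kg, a_d, trial.duration_min / 60.0
    )
    return CriticalLimit(
        inflection_time=t_star,
        pre_slope=infl.pre_slope,
        post_slope=infl.post_slope,
        critical_env=env,
        skin=skin,
        balance=balance,
        sweat=sweat,
    )
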