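"""Trial file format: a per-sample CSV plus a JSON metadata sidecar.

Schema (version 1)
------------------
``<trial_id>.csv`` — one row per sample with columns ``time_min, t_core_c,
t_chest_c, t_arm_c, t_thigh_c, t_leg_c, t_db_c`` and either ``p_a_mmhg`` or
``rh_pct`` (converted on read). ``<trial_id>.meta.json`` — subject
anthropometrics, activity, ramp schedule, pre/post nude masses, the two
gas-exchange readings, optional treadmill parameters and generator truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .calorimetry import GasExchange, SubjectProfile
from .protocol import TRIAL_COLUMNS, RampSchedule, TrialTimeSeries
from .psychro import vapor_pressure_from_rh

__all__ = ["SCHEMA_VERSION", "TrialSchemaError", "write_trial", "read_trial", "list_trials"]

SCHEMA_VERSION = 1


class TrialSchemaError(ValueError):
    """A trial file violates the documented schema."""


def write_trial(trial: TrialTimeSeries, out_dir: str | Path, truth=None) -> Path:
    """Write one trial as CSV + sidecar; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trial_id = trial.trial_id or "trial"
    csv_path = out_dir / f"{trial_id}.csv"
    trial.data.to_csv(csv_path, index=False, float_format="%.6g")

    meta = {
        "schema_version": SCHEMA_VERSION,
        "trial_id": trial_id,
        "subject": {
            "subject_id": trial.subject.subject_id,
            "height_m": trial.subject.height_m,
            "mass_kg": trial.subject.mass_kg,
            "age": trial.subject.age,
            "sex": trial.subject.sex,
        },
        "activity": trial.activity,
        "schedule": {
            "mode": trial.schedule.mode,
            "held_value": trial.schedule.held_value,
            "start_value": trial.schedule.start_value,
            "step_size": trial.schedule.step_size,
            "step_minutes": trial.schedule.step_minutes,
            "equilibration_minutes": trial.schedule.equilibration_minutes,
        },
        "mass_pre_kg": trial.mass_pre_kg,
        "mass_post_kg": trial.mass_post_kg,
        "gas": [
            {"time_min": t, "vo2_l_min": g.vo2, "rer": g.rer}
            for t, g in sorted(trial.gas.items())
        ],
        "treadmill_speed_ms": trial.treadmill_speed_ms,
        "treadmill_grade": trial.treadmill_grade,
    }
    meta.update(trial.meta)
    if truth is not None:
        meta["truth"] = dataclasses.asdict(truth) if dataclasses.is_dataclass(truth) else truth
    (out_dir / f"{trial_id}.meta.json").write_text(json.dumps(meta, indent=1))
    return csv_path


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise TrialSchemaError(msg)


def read_trial(csv_path: str | Path) -> TrialTimeSeries:
    """Read a trial CSV and its sidecar back into a :class:`TrialTimeSeries`.

    Raises :class:`TrialSchemaError` naming the offending column and the
    first offending CSV line (1-based, counting the header) on violations.
    """
    csv_path = Path(csv_path)
    meta_path = csv_path.with_suffix("").with_suffix(".meta.json")
    if not meta_path.exists():
        meta_path = csv_path.parent / (csv_path.stem + ".meta.json")
    _require(meta_path.exists(), f"missing metadata sidecar for {csv_path.name}")
    meta = json.loads(meta_path.read_text())
    _require(
        meta.get("schema_version") == SCHEMA_VERSION,
        f"unsupported schema_version {meta.get('schema_version')!r}",
    )

    df = pd.read_csv(csv_path)
    if "p_a_mmhg" not in df.columns and "rh_pct" in df.columns:
        df["p_a_mmhg"] = [
            vapor_pressure_from_rh(t, rh) for t, rh in zip(df["t_db_c"], df["rh_pct"])
        ]
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    _require(not missing, f"{csv_path.name}: missing columns {missing}")
    for col in TRIAL_COLUMNS:
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise TrialSchemaError(
                f"{csv_path.name}: non-numeric or missing {col} at line {bad[0] + 2}"
            )

    subj = meta["subject"]
    subject = SubjectProfile(
        height_m=subj["height_m"], mass_kg=subj["mass_kg"],
        age=subj["age"], sex=subj.get("sex", "unspecified"),
        subject_id=subj.get("subject_id", ""),
    )
    schedule = RampSchedule(**meta["schedule"])
    gas = {
        float(g["time_min"]): GasExchange(vo2=g["vo2_l_min"], rer=g["rer"])
        for g in meta.get("gas", [])
    }
    extra = {
        k: v
        for k, v in meta.items()
        if k not in {
            "schema_version", "trial_id", "subject", "activity", "schedule",
            "mass_pre_kg", "mass_post_kg", "gas", "treadmill_speed_ms", "treadmill_grade",
        }
    }
    return TrialTimeSeries(
        data=df[TRIAL_COLUMNS].astype(float),
        subject=subject,
        activity=meta["activity"],
        schedule=schedule,
        mass_pre_kg=meta["mass_pre_kg"],
        mass_post_kg=meta["mass_post_kg"],
        gas=gas,
        treadmill_speed_ms=meta.get("treadmill_speed_ms"),
        treadmill_grade=meta.get("treadmill_grade"),
        trial_id=meta.get("trial_id", csv_path.stem),
        meta=extra,
    )


def list_trials(in_dir: str | Path) -> list[Path]:
    """CSV paths of every trial in a directory (sorted for determinism)."""
    in_dir = Path(in_dir)
    return sorted(
        p.parent / (p.name[: -len(".meta.json")] + ".csv")
        for p in in_dir.glob("*.meta.json")
    )
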