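"""Run configuration: physical constants, detection thresholds, paths, seed.

A flat YAML mapping round-trips losslessly through :class:`RunConfig`. The
two clothing resistances default to the lumped values for a light summer
ensemble (~0.3 CLO); an ISO-9920 style adjustment for air movement is left
as an explicit no-op hook.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .calorimetry import I_T_DEFAULT, R_ET_DEFAULT
from .protocol import SLOPE_INCREASE_THRESHOLD

__all__ = ["RunConfig", "resultant_insulation"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs beyond the trial files themselves."""

    i_t: float = I_T_DEFAULT  # m2·degC·W^-1
    r_et: float = R_ET_DEFAULT  # m2·mmHg·W^-1
    c_res: float = 0.0  # W·m^-2, respiratory convective loss
    e_res: float = 0.0  # W·m^-2, respiratory evaporative loss
    s: float = 0.0  # W·m^-2, heat storage
    slope_threshold: float = SLOPE_INCREASE_THRESHOLD  # degC/h
    seed: int = 0
    out_dir: str = "out"
    activity: Optional[str] = None  # filter; None = all
    age_group: Optional[str] = None  # filter; None = all
    skin_weights: dict = field(
        default_factory=lambda: {"chest": 0.3, "arm": 0.2, "thigh": 0.3, "leg": 0.2}
    )

    def __post_init__(self) -> None:
        if self.i_t <= 0 or self.r_et <= 0:
            raise ValueError("clothing resistances must be positive")
        if abs(sum(self.skin_weights.values()) - 1.0) > 1e-9:
            raise ValueError("skin-site weights must sum to 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def resultant_insulation(i_t: float, air_velocity_ms: float = 0.0) -> float:
    """Hook for adjusting total insulation for air movement (ISO-9920 style).

    Chamber trials analysed here have negligible air movement, so this is a
    deliberate no-op returning ``i_t`` unchanged; it exists so a future
    resultant-insulation model slots in without touching callers.
    """
    return i_t
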