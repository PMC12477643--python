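"""Moist-air property conversions.

Every heat-balance term in this package needs one of three things from the
ambient air: the saturation vapor pressure over liquid water at some
temperature, the actual vapor pressure implied by a relative humidity, or
the (aspirated) wet-bulb temperature. Units follow chamber-physiology
convention throughout: temperatures in degrees Celsius, pressures in mmHg.

The saturation curve is the Arden Buck equation over liquid water, which is
accurate to well under 0.1% across the physiologic and chamber range
(0–60 degC). Wet-bulb temperature is recovered by bisecting the classic
psychrometer relation at standard barometric pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "EnvironmentState",
    "saturation_vapor_pressure",
    "vapor_pressure_from_rh",
    "rh_from_vapor_pressure",
    "wet_bulb_temperature",
    "HPA_TO_MMHG",
    "BAROMETRIC_PRESSURE_MMHG",
    "PSYCHROMETER_COEFF",
]

#: hectopascal -> millimetre of mercury
HPA_TO_MMHG = 0.750062

#: standard sea-level barometric pressure (mmHg); chamber altitude assumed ~0
BAROMETRIC_PRESSURE_MMHG = 760.0

#: psychrometer coefficient A for a ventilated sensor (degC^-1), used in
#: p_a = p_sat(t_wb) - A * P_bar * (t_db - t_wb)
PSYCHROMETER_COEFF = 6.6e-4

_T_MIN, _T_MAX = -20.0, 110.0


def saturation_vapor_pressure(t: float) -> float:
    """Saturation vapor pressure over liquid water, in mmHg.

    Arden Buck formulation (1981, liquid-water branch), converted from hPa.

    Parameters
    ----------
    t : float
        Air or surface temperature in degC; valid for -20 <= t <= 110.

    Raises
    ------
    ValueError
        If ``t`` is outside the supported range.
    """
    if not (_T_MIN <= t <= _T_MAX):
        raise ValueError(
            f"temperature {t!r} degC outside supported range [{_T_MIN}, {_T_MAX}]"
        )
    e_hpa = 6.1121 * math.exp((18.678 - t / 234.5) * t / (257.14 + t))
    return e_hpa * HPA_TO_MMHG


def vapor_pressure_from_rh(t_db: float, rh: float) -> float:
    """Ambient vapor pressure (mmHg) from dry-bulb temperature and rh (%)."""
    if not (0.0 <= rh <= 100.0):
        raise ValueError(f"relative humidity {rh!r}% outside [0, 100]")
    return rh / 100.0 * saturation_vapor_pressure(t_db)


def rh_from_vapor_pressure(t_db: float, p_a: float) -> float:
    """Relative humidity (%) from dry-bulb temperature and vapor pressure."""
    p_sat = saturation_vapor_pressure(t_db)
    if p_a < 0.0 or p_a > p_sat * (1.0 + 1e-12):
        raise ValueError(
            f"vapor pressure {p_a!r} mmHg outside [0, p_sat({t_db}) = {p_sat:.3f}]"
        )
    return 100.0 * p_a / p_sat


def wet_bulb_temperature(
    t_db: float,
    p_a: float,
    *,
    pressure_mmhg: float = BAROMETRIC_PRESSURE_MMHG,
    tol: float = 1e-8,
) -> float:
    """Aspirated wet-bulb temperature (degC) by bisection.

    Solves ``p_a = p_sat(t_wb) - A * P * (t_db - t_wb)`` for ``t_wb``. The
    left side of the residual is strictly increasing in ``t_wb``, so the
    root is unique and bisection cannot stall on ties.
    """
    if p_a < 0.0:
        raise ValueError("vapor pressure must be non-negative")
    p_sat_db = saturation_vapor_pressure(t_db)
    if p_a > p_sat_db * (1.0 + 1e-9):
        raise ValueError(
            f"supersaturated input: p_a={p_a} > p_sat({t_db})={p_sat_db:.3f}"
        )

    def residual(t_wb: float) -> float:
        return (
            saturation_vapor_pressure(t_wb)
            - PSYCHROMETER_COEFF * pressure_mmhg * (t_db - t_wb)
            - p_a
        )

    # saturated air: wet bulb equals dry bulb
    if residual(t_db) <= 0.0:
        return t_db
    lo, hi = _T_MIN, t_db
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class EnvironmentState:
    """One chamber condition: dry-bulb temperature plus ambient humidity.

    Exactly one of ``p_a`` (mmHg) or ``rh`` (%) must be supplied; the other
    is derived, and if both are given they must agree to 0.5% relative.
    ``t_wb`` is computed lazily via :func:`wet_bulb_temperature`.
    """

    t_db: float
    p_a: Optional[float] = None
    rh: Optional[float] = None
    t_wb: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.p_a is None and self.rh is None:
            raise ValueError("EnvironmentState needs p_a or rh")
        if self.p_a is None:
            object.__setattr__(self, "p_a", vapor_pressure_from_rh(self.t_db, self.rh))
        elif self.rh is None:
            object.__setattr__(self, "rh", rh_from_vapor_pressure(self.t_db, self.p_a))
        else:
            implied = vapor_pressure_from_rh(self.t_db, self.rh)
            if implied > 0 and abs(self.p_a - implied) > 0.005 * implied:
                raise ValueError(
                    f"rh={self.rh}% implies p_a={implied:.3f} mmHg, "
                    f"inconsistent with supplied p_a={self.p_a}"
                )
        p_sat = saturation_vapor_pressure(self.t_db)
        if not (0.0 <= self.p_a <= p_sat * (1.0 + 1e-9)):
            raise ValueError(f"p_a={self.p_a} outside [0, saturation={p_sat:.3f}]")
        if self.t_wb is None:
            object.__setattr__(
                self, "t_wb", wet_bulb_temperature(self.t_db, self.p_a)
            )
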