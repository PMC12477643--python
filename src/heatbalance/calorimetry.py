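"""Partitional-calorimetry flux terms and maximal skin wettedness.

The heat balance of a person in a hot chamber is decomposed into a net
metabolic term (indirect calorimetry minus external work), dry
radiative+convective exchange through a lumped clothing insulation, and the
evaporation required to close the budget. Dividing that requirement by the
environment's maximal evaporative capacity at fully wet skin gives the skin
wettedness needed for balance; evaluated at the last compensable
environment of a ramp trial, this ratio is the maximal skin wettedness
(omega_max). All fluxes are normalised to the DuBois body surface area and
expressed in W·m^-2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .psychro import saturation_vapor_pressure

__all__ = [
    "SubjectProfile",
    "GasExchange",
    "SkinTemperatures",
    "HeatBalanceResult",
    "SweatSummary",
    "UncompensableDryLimitError",
    "dubois_area",
    "mean_skin_temperature",
    "metabolic_rate",
    "external_work",
    "dry_heat_exchange",
    "evaporative_capacity",
    "required_evaporation",
    "max_skin_wettedness",
    "skin_evaporation",
    "sweat_rate",
    "I_T_DEFAULT",
    "R_ET_DEFAULT",
    "SKIN_SITE_WEIGHTS",
    "EE_RER_07",
    "EE_RER_10",
    "MPH_TO_MS",
]

log = logging.getLogger(__name__)

#: lumped total dry insulation skin->environment, m2·degC·W^-1 (~0.3 CLO ensemble)
I_T_DEFAULT = 0.163
#: lumped total evaporative resistance skin->environment, m2·mmHg·W^-1
R_ET_DEFAULT = 0.13
#: four-site weighting for mean skin temperature (chest, arm, thigh, leg)
SKIN_SITE_WEIGHTS = {"chest": 0.3, "arm": 0.2, "thigh": 0.3, "leg": 0.2}
#: energy equivalent of oxygen at the RER interpolation endpoints, kJ·L^-1
EE_RER_07 = 19.62
EE_RER_10 = 21.13
#: miles per hour -> metres per second
MPH_TO_MS = 0.44704


class UncompensableDryLimitError(ValueError):
    """Ambient vapor pressure at or above skin saturation: E_max <= 0.

    Raised instead of returning a non-positive evaporative capacity so a
    fully uncompensable (dry-limit) environment is flagged, never silently
    propagated as a negative flux or NaN.
    """


def dubois_area(height_m: float, mass_kg: float) -> float:
    """DuBois body surface area (m^2): 0.007184 · mass^0.425 · height_cm^0.725."""
    if height_m <= 0 or mass_kg <= 0:
        raise ValueError("height and mass must be positive")
    return 0.007184 * mass_kg**0.425 * (height_m * 100.0) ** 0.725


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics plus the derived surface area that normalises fluxes."""

    height_m: float
    mass_kg: float
    age: float
    sex: str = "unspecified"
    subject_id: str = ""
    a_d: float = field(init=False)
    ad_per_mass: float = field(init=False)

    def __post_init__(self) -> None:
        a_d = dubois_area(self.height_m, self.mass_kg)
        object.__setattr__(self, "a_d", a_d)
        object.__setattr__(self, "ad_per_mass", a_d / self.mass_kg)


@dataclass(frozen=True)
class GasExchange:
    """One open-circuit spirometry measurement: VO2 (L·min^-1) and RER.

    RER outside the metabolisable range [0.7, 1.0] (hyperventilation
    artifacts) is clamped with a warning, since the oxygen energy
    equivalent is only defined on that interval.
    """

    vo2: float
    rer: float

    def __post_init__(self) -> None:
        if self.vo2 <= 0:
            raise ValueError(f"vo2 must be positive, got {self.vo2}")
        if not (0.7 <= self.rer <= 1.0):
            clamped = min(max(self.rer, 0.7), 1.0)
            log.warning("RER %.3f outside [0.7, 1.0]; clamped to %.2f", self.rer, clamped)
            warnings.warn(
                f"RER {self.rer} outside [0.7, 1.0]; clamped to {clamped}",
                stacklevel=2,
            )
            object.__setattr__(self, "rer", clamped)


@dataclass(frozen=True)
class SkinTemperatures:
    """Four-site skin temperatures (degC) with the weighted mean."""

    t_chest: float
    t_arm: float
    t_thigh: float
    t_leg: float

    @property
    def t_sk_bar(self) -> float:
        return mean_skin_temperature(self.t_chest, self.t_arm, self.t_thigh, self.t_leg)


@dataclass(frozen=True)
class SweatSummary:
    """Whole-body sweat rate (g·m^-2·h^-1) and percent body mass loss."""

    sr: float
    bml_pct: float


@dataclass(frozen=True)
class HeatBalanceResult:
    """All flux terms (W·m^-2) and the wettedness ratio at one condition.

    ``omega_max`` is deliberately not clamped at 1: values above 1 indicate
    the balance requirement exceeds even a fully wet skin's capacity.
    """

    m: float
    w_ext: float
    m_net: float
    rc: float
    e_max: float
    e_req: float
    omega_max: float
    p_s_sk: float
    c_res: float = 0.0
    e_res: float = 0.0
    s: float = 0.0


def mean_skin_temperature(
    t_chest: float, t_arm: float, t_thigh: float, t_leg: float
) -> float:
    """Four-site weighted mean skin temperature (degC).

    Weights 0.3/0.2/0.3/0.2 for chest/arm/thigh/leg. Sites outside the
    physiologic band [25, 42] degC indicate sensor faults and are rejected.
    """
    for name, t in (("chest", t_chest), ("arm", t_arm), ("thigh", t_thigh), ("leg", t_leg)):
        if not (25.0 <= t <= 42.0):
            raise ValueError(f"skin site {name}={t} degC outside physiologic [25, 42]")
    return 0.3 * t_chest + 0.3 * t_thigh + 0.2 * t_arm + 0.2 * t_leg


def oxygen_energy_equivalent(rer: float) -> float:
    """Energy equivalent of oxygen (kJ·L^-1), linear in RER on [0.7, 1.0].

    The interpolation weight is formed so both endpoints are recovered
    exactly in floating point.
    """
    frac = (rer - 0.7) / (1.0 - 0.7)
    return frac * EE_RER_10 + (1.0 - frac) * EE_RER_07


def metabolic_rate(gas: GasExchange, a_d: float) -> float:
    """Metabolic rate M (W·m^-2) from VO2 and RER, normalised to DuBois area.

    M = VO2 [L·min^-1] · ee(RER) [kJ·L^-1] / 60 · 1000 / A_D.
    """
    if a_d <= 0:
        raise ValueError("surface area must be positive")
    return gas.vo2 * oxygen_energy_equivalent(gas.rer) / 60.0 * 1000.0 / a_d


def external_work(m_b: float, v_w: float, f_g: float, a_d: float) -> float:
    """External work rate of graded treadmill walking (W·m^-2).

    W = 9.81 · m_b · v_w · F_g / A_D, the rate of potential-energy gain
    against gravity. Downhill (negative grade) is out of scope.
    """
    if v_w < 0:
        raise ValueError("walking velocity must be non-negative")
    if not (0.0 <= f_g < 1.0):
        raise ValueError(f"fractional grade {f_g} outside [0, 1)")
    if a_d <= 0:
        raise ValueError("surface area must be positive")
    return 9.81 * m_b * v_w * f_g / a_d


def dry_heat_exchange(t_db: float, t_sk_bar: float, i_t: float = I_T_DEFAULT) -> float:
    """Dry (radiative + convective) heat exchange R+C (W·m^-2).

    (R+C) = (T_db - T_sk_bar) / I_T; positive means the body gains heat
    from the environment.
    """
    if i_t <= 0:
        raise ValueError("total insulation i_t must be positive")
    return (t_db - t_sk_bar) / i_t


def evaporative_capacity(
    t_sk_bar: float, p_a: float, r_et: float = R_ET_DEFAULT
) -> tuple[float, float]:
    """Maximal evaporative capacity of the environment.

    Returns ``(e_max, p_s_sk)`` where ``p_s_sk`` is the saturation vapor
    pressure at the skin surface (100% rh at skin temperature) and
    E_max = (P_s,sk - P_a) / R_e,t.

    Raises
    ------
    UncompensableDryLimitError
        If the ambient vapor pressure is at or above skin saturation, so no
        evaporation is possible (E_max <= 0).
    """
    if r_et <= 0:
        raise ValueError("evaporative resistance r_et must be positive")
    p_s_sk = saturation_vapor_pressure(t_sk_bar)
    e_max = (p_s_sk - p_a) / r_et
    if e_max <= 0.0:
        raise UncompensableDryLimitError(
            f"ambient vapor pressure {p_a:.2f} mmHg >= skin saturation "
            f"{p_s_sk:.2f} mmHg: evaporative capacity non-positive"
        )
    return e_max, p_s_sk


def required_evaporation(
    m_net: float,
    rc: float,
    c_res: float = 0.0,
    e_res: float = 0.0,
    s: float = 0.0,
) -> float:
    """Evaporation required for heat balance: E_req = M_net + (R+C) + C_res - E_res - S.

    Respiratory terms and heat storage default to 0 (negligible at these
    metabolic rates) but stay explicit so a non-zero storage hook can use
    the full budget.
    """
    return m_net + rc + c_res - e_res - s


def max_skin_wettedness(e_req: float, e_max: float) -> float:
    """Skin wettedness required for balance: omega = E_req / E_max, unclamped."""
    if e_max <= 0:
        raise UncompensableDryLimitError(
            f"e_max={e_max} non-positive; wettedness undefined"
        )
    return e_req / e_max


def skin_evaporation(
    omega: float, p_s_sk: float, p_a: float, r_et: float = R_ET_DEFAULT
) -> float:
    """Evaporative heat loss from skin at wettedness omega (W·m^-2).

    E_sk = omega · (P_s,sk - P_a) / R_e,t; equals the full evaporative
    capacity at omega = 1.
    """
    if omega < 0:
        raise ValueError("wettedness must be non-negative")
    if r_et <= 0:
        raise ValueError("evaporative resistance r_et must be positive")
    if p_s_sk - p_a <= 0.0:
        raise UncompensableDryLimitError(
            f"ambient vapor pressure {p_a:.2f} mmHg >= skin saturation "
            f"{p_s_sk:.2f} mmHg"
        )
    return omega * (p_s_sk - p_a) / r_et


def sweat_rate(
    mass_pre: float, mass_post: float, a_d: float, duration_h: float
) -> SweatSummary:
    """Whole-body sweat rate and %BML from nude body-mass loss.

    SR = Δmass·1000 / A_D / duration; a mass gain (fluid retention or scale
    error) is clamped to zero with a warning rather than reported negative.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if a_d <= 0:
        raise ValueError("surface area must be positive")
    loss = mass_pre - mass_post
    if loss < 0:
        log.warning("mass gain of %.3f kg; sweat rate clamped to 0", -loss)
        warnings.warn("post-trial mass exceeds pre-trial mass; SR clamped at 0", stacklevel=2)
        loss = 0.0
    return SweatSummary(
        sr=loss * 1000.0 / a_d / duration_h,
        bml_pct=100.0 * loss / mass_pre,
    )
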