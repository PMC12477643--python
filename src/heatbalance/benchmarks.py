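"""Published group-mean critical environmental limits used as cross-check anchors.

These are cohort means at the upper limit of compensable heat stress for
unacclimated young (18–33 yr) and older (65–92 yr) adults at three low
metabolic rates, across humidity-ramp conditions (dry-bulb held at 34, 36,
38 or 40 degC) and temperature-ramp conditions (vapor pressure held at 12,
16 or 20 mmHg). Columns: dry-bulb temperature (degC), relative humidity
(%), wet-bulb temperature (degC), ambient vapor pressure (mmHg), sweat rate
(g·m^-2·h^-1), mean skin temperature (degC), dry heat gain R+C (W·m^-2),
required and maximal evaporation (W·m^-2), and maximal skin wettedness.

They serve as fixed inputs for consistency checks of the flux arithmetic
(e.g. recomputing R+C, E_max and omega_max from the printed temperatures
and pressures); they are not outputs of this package. Wettedness entries
are means of per-subject ratios, so in humid cells they can differ from the
ratio of the mean fluxes by ~0.01.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_conditions", "REFERENCE_TABLES"]

_COLS = ["t_db", "rh", "t_wb", "p_a", "sr", "t_sk_bar", "rc", "e_req", "e_max", "omega_max"]

_YOUNG_MINACT = {
    "34C":    [33.9, 79.7, 30.8, 31.7, 122, 36.2, -14,  70, 101, 0.71],
    "36C":    [36.0, 66.5, 30.4, 29.6, 140, 36.3,  -2,  74, 115, 0.65],
    "38C":    [38.1, 46.9, 31.1, 29.6, 196, 36.5,  10, 144, 169, 0.73],
    "40C":    [40.1, 36.8, 30.6, 27.6, 178, 37.7,  21, 156, 184, 0.65],
    "12mmHg": [49.3, 13.8, 25.5, 12.2, 167, 38.5,  66, 155, 297, 0.52],
    "16mmHg": [46.4, 20.7, 26.9, 16.3, 142, 38.0,  52, 137, 259, 0.53],
    "20mmHg": [43.7, 29.5, 27.8, 19.7, 121, 37.5,  38, 122, 221, 0.55],
}

_YOUNG_LIGHTAMB = {
    "34C":    [33.8, 60.8, 27.4, 24.0, 179, 35.9, -13, 125, 155, 0.82],
    "36C":    [35.9, 54.6, 28.0, 24.2, 205, 35.8,   0, 132, 151, 0.88],
    "38C":    [38.1, 60.9, 28.2, 23.0, 269, 36.6,   9,  88, 117, 0.84],
    "40C":    [40.0, 51.0, 27.2, 20.9, 291, 37.0,  18,  99, 141, 0.83],
    "12mmHg": [44.5, 18.6, 24.1, 12.1, 223, 37.4,  38, 180, 279, 0.65],
    "16mmHg": [42.5, 25.6, 25.7, 16.0, 194, 37.1,  32, 163, 241, 0.68],
    "20mmHg": [39.1, 37.9, 26.8, 20.0, 197, 36.0,  19, 152, 188, 0.82],
}

_OLDER_REST = {
    "34C":    [33.9, 59.2, 26.9, 23.5,  48, 35.5, -10,  39, 151, 0.28],
    "36C":    [36.2, 60.0, 29.2, 26.9,  51, 36.2,   0,  46, 133, 0.36],
    "38C":    [38.1, 53.4, 29.5, 26.7,  91, 36.4,  11,  60, 137, 0.48],
    "40C":    [40.1, 37.7, 27.4, 21.6,  75, 36.7,  20,  72, 187, 0.40],
    "12mmHg": [46.3, 15.6, 24.4, 11.7,  58, 37.3,  48,  93, 286, 0.33],
    "16mmHg": [43.4, 25.0, 25.9, 16.1,  49, 36.8,  37,  88, 232, 0.37],
}

_OLDER_MINACT = {
    "34C":    [33.8, 58.4, 26.8, 23.1,  78, 35.6, -11,  66, 154, 0.47],
    "36C":    [36.2, 52.8, 27.8, 24.9,  87, 36.3,  -1,  75, 152, 0.52],
    "38C":    [38.0, 46.1, 27.8, 23.0, 117, 36.6,   9,  88, 171, 0.52],
    "40C":    [40.2, 33.7, 26.4, 19.5,  90, 37.2,  18, 103, 219, 0.49],
    "12mmHg": [42.9, 18.8, 23.5, 11.9,  91, 37.4,  34, 111, 281, 0.39],
    "16mmHg": [40.4, 31.5, 24.5, 15.8,  85, 36.4,  24,  98, 227, 0.43],
}

REFERENCE_TABLES = {
    ("young", "MinAct"): _YOUNG_MINACT,
    ("young", "LightAmb"): _YOUNG_LIGHTAMB,
    ("older", "rest"): _OLDER_REST,
    ("older", "MinAct"): _OLDER_MINACT,
}


def reference_conditions(age_group: str, activity: str) -> pd.DataFrame:
    """Group-mean critical-limit table for one cohort × activity.

    Rows are environmental conditions (held value of the ramp), columns as
    documented in the module docstring.
    """
    try:
        raw = REFERENCE_TABLES[(age_group, activity)]
    except KeyError:
        raise KeyError(
            f"no reference table for age_group={age_group!r}, activity={activity!r}"
        ) from None
    return pd.DataFrame.from_dict(raw, orient="index", columns=_COLS)
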