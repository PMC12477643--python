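# Methods

## Scope and assumptions

The package analyses progressive heat-stress trials in which one
environmental variable ramps stepwise (1 °C or 1 mmHg every 5 min after a
30-min equilibration) while the other is held, and a subject works at a
fixed low metabolic rate. Its core assumptions:

- While the environment is compensable, core temperature is at a quasi
  steady state, so heat storage S ≈ 0 and the budget closes through
  evaporation; the upward core-temperature inflection marks the point where
  this stops holding.
- The 5-min window immediately preceding the inflection (half-open,
  `[t*−5, t*)`; samples at exactly t\* excluded) represents the *final
  compensable* condition, and all fluxes are evaluated on window averages.
- Clothing and boundary air are lumped into two scalar resistances: total
  insulation I_T and total evaporative resistance R_e,t. Radiant and
  convective exchange are not partitioned; mean radiant temperature is
  assumed equal to dry-bulb (indoor chamber, low air movement).
- Respiratory convective and evaporative losses (<1 and ≤2 W·m⁻² at these
  workloads) default to zero but remain explicit parameters of
  `required_evaporation`, so a storage or respiratory model can be slotted
  in without changing the budget arithmetic.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `i_t` | 0.163 | m²·°C·W⁻¹ | total dry insulation, skin→environment (~0.3 CLO ensemble) |
| `r_et` | 0.13 | m²·mmHg·W⁻¹ | total evaporative resistance |
| skin weights | 0.3/0.2/0.3/0.2 | — | chest/arm/thigh/leg weighting of T̄_sk |
| `slope_threshold` | 0.1 | °C·h⁻¹ | minimum slope increase for an admissible breakpoint |
| ee endpoints | 19.62, 21.13 | kJ·L⁻¹ O₂ | oxygen energy equivalent at RER 0.7 and 1.0 |
| treadmill (LightAmb) | 0.9835 m·s⁻¹, 3% | — | 2.2 mi·h⁻¹ walking speed and fractional grade |
| barometric pressure | 760 | mmHg | sea-level chamber assumed (altitude not modelled) |

`resultant_insulation` is a deliberate no-op hook: adjusting I_T for air
movement (ISO-9920 style) is out of scope but callers already route through
it.

## Psychrometrics

Saturation vapor pressure uses the Arden Buck equation over liquid water,
converted hPa→mmHg (×0.750062). Buck is accurate to well under 1% across
0–60 °C; the test suite cross-checks it against the Antoine equation as an
independent formulation. The printed evaporative-capacity anchors constrain
the choice of curve only to about ±3%, which is the tolerance used where
E_max is compared.

Wet-bulb temperature solves the ventilated-psychrometer relation
`p_a = p_sat(t_wb) − A·P·(t_db − t_wb)` with A = 6.6×10⁻⁴ °C⁻¹ at
P = 760 mmHg, by bisection to 1e-8 °C. The residual is strictly monotone in
t_wb, so the root is unique and tie-free.

## Inflection detection

No published operational criterion exists for "a clear upward inflection",
so the package adopts the simplest reproducible one: a continuous
two-segment linear least-squares fit (hinge basis `1, t, (t−b)+`), with the
breakpoint b searched exhaustively on a 1-min grid leaving ≥5 min of data
per segment. A candidate is admissible when the slope increase is at least
0.1 °C·h⁻¹ and the post-breakpoint slope is positive; among admissible
candidates the minimal-SSE breakpoint wins, ties resolved to the earliest
(the conservative choice — an earlier limit implies a lower critical
environment). If no candidate is admissible the trial is reported as
compensable throughout (`no-inflection`), flagged rather than dropped.
Equilibration data are excluded from the fit (transient drift), and
sampling gaps >2 min are linearly interpolated onto a 1-min grid with a
warning. On series of ≤200 points the implementation is verified to agree
exactly with an independently parameterised exhaustive search.

## Synthetic generator

The generator emulates exactly the structure the analysis consumes:

- **Environment**: piecewise-constant ramp per the schedule; humidity ramps
  are truncated at saturation.
- **Core temperature**: baseline + pre-slope (default 0) until the onset of
  step k+1 — k being the true critical step — then an added linear rise
  (default 0.6 °C·h⁻¹), plus i.i.d. Gaussian noise (default σ = 0.05 °C).
  Samples every 15 s, the epoch at which ingestible telemetry capsules
  record.
- **Skin temperatures**: a linear function of dry-bulb temperature
  (intercept 30.8, slope 0.155) capped at 38.5 °C — placing T̄_sk in the
  observed 35.5–38.5 °C band over 34–50 °C chambers — with fixed site
  offsets whose weighted sum is zero and per-site noise σ = 0.15 °C. These
  are descriptive coefficients, not a thermophysiological model.
- **Gas exchange**: two readings (5 and 60 min) drawn around the activity
  target (90 W rest, 150 W MinAct, 250 W LightAmb), RER ~ N(0.84, 0.02)
  clipped to [0.75, 0.95], VO₂ with 5% CV.
- **Mass loss**: exactly sweat-rate × A_D × duration, so the analysed sweat
  rate reproduces the prescribed level to rounding.

`build_study` calibrates each subject's ramp start value so the noise-free
wettedness at the true critical step equals a target exactly: for a
humidity ramp the held dry-bulb fixes T̄_sk, (R+C) and P_s,sk, giving the
closed form p_a\* = P_s,sk − R_e,t·E_req/ω. One seeded generator drives all
draws; trial metadata records the truth.

What the generator does **not** emulate: cardiovascular or sweating
dynamics, acclimation, core-temperature lag behind the environment step
(the true inflection coincides with the step boundary), within-trial drift
of metabolic rate, or skin-temperature response to humidity at fixed
dry-bulb. Passing recovery tests therefore demonstrate the correctness of
the detection and flux arithmetic under the stated noise model, not
robustness to physiological confounds in real traces.

## Statistics

Cells are summarised as mean with a Student-t 95% CI from the cell's own
SD. Independent contrasts use the Welch unequal-variance t-test by default
(pooled available via `welch=False`); paired contrasts use the paired t.
The per-comparison threshold is Bonferroni-adjusted, α = 0.05/m (0.008 at
m = 6, 0.007 at m = 7 to the printed precision). Note that cohort-mean
wettedness is a mean of per-subject ratios; in humid conditions it can
differ from the ratio of mean fluxes by ~0.01, which is why ratio-based
cross-checks are held to the printed 2-decimal precision rather than exact
rounding.

## Numerical and formatting choices

- RER outside [0.7, 1.0] is clamped with a warning (the energy-equivalent
  interpolation is undefined outside); the interpolation weight is formed
  as `(rer−0.7)/(1.0−0.7)` so both endpoints are exact in floating point.
- ω_max is never clamped at 1; E_max ≤ 0 raises a distinct
  uncompensable-dry-limit error instead of propagating NaN or a negative
  capacity.
- A post-trial mass gain clamps sweat rate at 0 with a warning.
- Table rendering rounds fluxes to integers, wettedness to 2 decimals,
  temperatures and pressures to 0.1.

## Problem sizes

Recovery properties run at 200 seeded replicates for breakpoint detection,
10–40 subjects for end-to-end cohort recovery, and 300–500 replicates for
the coverage/power checks — sizes at which the binomial uncertainty of the
measured rates is small relative to the asserted margins.

## Known limitations

- The two lumped resistances are constants; no resultant-insulation
  adjustment for air velocity or posture is applied.
- Breakpoint detection assumes a single upward kink; multi-phase drifts or
  transient dips are fit as best as a two-segment line allows. Alternative
  detectors (e.g. Bayesian change-point) are extension points only.
- The bundled group-mean reference conditions are cross-check inputs with
  2–3 significant digits; recomputed fluxes inherit that granularity.
- Subject-level inference on real cohorts (age-group differences at each
  environment) requires the original per-subject data; the package verifies
  its machinery on synthetic cohorts instead.
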