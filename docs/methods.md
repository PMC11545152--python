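# Methods

## Plant model

The house is a single well-mixed air node with heat capacity ρVcp
(1.2 kg/m³ × 6375 m³ × 1006 J/(kg·°C) ≈ 7.70 MJ/°C). Gains are solar
radiation through the envelope and flock sensible heat; losses are the two
ventilation branches, floor convection and envelope conduction. Lighting and
equipment gains and infiltration are neglected as minor. There is no
humidity, gas or spatial state: the model intentionally trades CFD fidelity
for a plant fast enough to close a control loop at 1-minute resolution over
multi-day horizons.

**Parameters.** The default geometry describes a 100 × 15 × 4 m house for
48,000 white-feather layers: volume 6375 m³, floor 1500 m², envelope 920 m²
(k = 0.93 W/(m²·°C)), solar-receiving area 1491 m² with radiation conversion
coefficient 0.64, floor film coefficient 6 W/(m²·°C), pad thickness 0.15 m.
Flock mass defaults to 92,900 kg, back-solved from the design ventilation
rates (0.08 and 0.02 m³/(min·kg) against the 7435 / 1858 m³/min limits,
≈1.94 kg/bird); egg yield 2600 kg/day (~90 % lay × 60 g). A roof-exchange
coefficient (5.4 W/(m²·K)), insulation-board conductance (0.042) and total
pad area (1504 m²) are carried in the config for completeness but enter no
default flux.

**Flock heat.** The metabolic law `6.28 m^0.75 + 25 Y` is a per-animal
allometry; the budget evaluates it at the mean bird mass and sums over the
flock (≈560 kW total at 20 °C, ~10 W sensible-plus-latent per hen), which
is the magnitude the CIGR guideline intends. Evaluating the same expression
once with the total flock mass would yield ~33 kW — an order of magnitude
too little heat to keep a winter house warm — so the per-animal form is the
default; setting `flock_count=1` recovers the aggregate reading. The
sensible fraction polynomial is clamped to [0, 1] since it leaves the
physical range at extreme temperatures.

**Cooling pad.** The pad outlet approaches the outdoor wet-bulb with
residual fraction `E = exp(−12.28305 v^−0.30078 H)` of the wet-bulb
depression, where `v` is the branch face velocity. This reading of the
decay exponent yields 55–85 % saturation effectiveness at face velocities
of 1.5–20 m/s, matching documented pad performance; an alternative reading
that multiplies the exponent by ρcp drives the pad to an all-or-nothing
cooler and is retained only as the config switch `pad_exponent_literal`
for sensitivity work. Below a 10⁻⁶ m/s velocity floor the outlet is
defined as the wet-bulb (the associated mass flow is ~0, so the flux is
unaffected); this keeps the v → 0 limit continuous.

**Ventilation split.** With total exhaust flow L and split λ, the
positive-pressure branch carries λL through a 6.7 m² fan bank (95 × 300 mm
fans) and the guide plates carry (1−λ)L through ≈4 m² of slots (plates open
only 10–20° from the wall). Because the guide-plate section is the smaller,
raising λ lowers the dominant face velocity and improves pad effectiveness —
the split behaves as the rule base intends (hotter house → larger λ → more
cooling). Note the effectiveness-weighted mixture has an interior optimum
near λ ≈ 0.6–0.8 at full flow; commanding λ = 1 is slightly poorer than the
optimum, which matters for the variable-universe controller (below).

**Boundary substitutions.** When a driver supplies no wall temperatures,
the inner surface is taken as the current indoor temperature and the outer
surface as the outdoor dry-bulb; the floor/manure-pit temperature comes
from the driver (synthetic mode: daily-mean outdoor temperature plus a
seasonal offset that places the pit near the indoor range, since the pit
sits inside the heated house).

**Integration.** Explicit Euler at dt = 60 s, matching the 1-minute data
cadence; a classical RK4 stepper backs the convergence tests. The Euler
step is stable for flows up to ≈2V/dt ≈ 212 m³/s, well above the 124 m³/s
actuator ceiling. Equilibria found by the trajectory agree with
independently bisected roots of the heat budget to < 0.01 °C.

## Controllers

All variants act through the same reverse-acting actuator map: commanded
flow = `clip(L_min + max(0, −60·u), L_min, L_max)` in m³/min. The factor 60
makes the controller output `u` live on the SI (m³/s) flow scale, on which
the seasonal gains (summer 23/15/3, autumn 17/13/8, winter 13/12/4, for
setpoints 27.5/27/25.5 °C) produce minute-scale response across the
1858–7435 m³/min actuator span. The integral accumulates per control step
(rectangle rule) and is clamped so the integral term alone can never exceed
the actuator span (anti-windup).

**On–off baseline.** Two-level thermostat with a symmetric ±0.5 °C
hysteresis band, holding its previous output inside the band.

**Fuzzy stage.** Seven evenly spaced triangular sets with 50 % overlap per
variable (inputs clipped at the universe bounds, so the end terms act as
shoulders), min activation, max aggregation. Initial universes: e ∈ [−3, 3]
°C, ec ∈ [−1.5, 1.5] °C/step, output U ∈ [−5, 5]. The ΔK channels are
defuzzified by area centroid on a 201-point grid; the λ channel uses the
height (center-of-sets) method with the seven term centers mapped affinely
onto [0, 1], so a pure NB/PB verdict yields exactly 0/1. Per-channel output
scale factors (default 1) are exposed for sensitivity studies. With the
fuzzy stage disabled the law reduces bit-exactly to the fixed-gain PID.

**Variable universe.** Every control step the e, ec and output universes
are rescaled by `α = (|x|/E)^P + θ` (θ = 10⁻⁴) and
`β = (α_e + α_ec)/2 + θ`, with the shared exponent
`P = E1/(|e|(E1+E2)+v) + E2/(|ec|(E1+E2)+v)` capped at 1 (v = 10⁻⁶).
The λ channel keeps its initial universe system and is inferred from the
unscaled memberships: only the e/ec/U domains take part in the rescaling,
and contracting λ's inputs would reduce the split to the sign of the error
and slam the inlet configuration at every zero-crossing. With all scaling
factors frozen at 1 the variant is bit-identical to the plain fuzzy PID.

**Discrete-sampling behaviour.** Two properties of the closed loop follow
from the 60 s cadence and are worth knowing before comparing controllers:

1. The printed seasonal gains sit near the discrete stability boundary. On
   a constant mild summer driver the fixed-gain PID holds a bounded
   ±0.8 °C period-2 cycle, which the fuzzy gain corrections damp to
   machine-level tracking; in a continuous-time loop the same gains are
   stable. The package keeps the 1-minute cadence as a modelling choice
   aligned with the data resolution.
2. The adaptive exponent caps at P = 1 whenever *either* |e| or |ec| is
   small — on a slow thermal plant, nearly always. With P = 1,
   α = |e|/E places the fuzzified error exactly at the contracted-universe
   edge, so the ΔK stage behaves like a relay whose output amplitude scales
   with β ∝ |e|: a sliding-mode-like regime. At 1-minute sampling the
   associated chatter has visible amplitude (~±0.4 °C) in the regulation
   band, which costs the variable-universe variant a few percent of MAE
   relative to the plain fuzzy PID on the standardized battery, while it
   still clearly beats PID and on–off control and commands the expected
   seasonal split ordering (mean λ ≈ 0.30 on hot summer drivers vs ≈ 0 in
   winter). At fast sampling the same mechanism chatters at negligible
   amplitude — the ranking between the two fuzzy variants is therefore a
   function of the control period, not a fixed property of the algorithms.

## Synthetic weather

The generator emulates the published per-day summaries of the monitored
seasons; it does not attempt real weather. Outdoor dry-bulb follows a
smooth diurnal curve pinned exactly to the day's minimum at 05:00 and
maximum at 15:00; the cooling branch is a half-cosine raised to an exponent
solved by bisection so the noise-free daily mean equals the published daily
average (clear winter days are strongly skewed; one published autumn mean
lies below what any such curve can reach, and saturates at the exponent
clamp). Irradiance is a clear-sky half-sine between sunrise and sunset
(peaks 850/600/400 W/m² by season). Relative humidity is anti-correlated
with temperature (−1.5 %/°C about the profile mean) around the published
mean RH — the published humidity summary is the indoor mean, used here as
an outdoor proxy for lack of an outdoor figure. Minute-scale variability is
a seeded AR(1) process (φ = 0.95, marginal σ = 0.3 °C by default; doubled
for RH). The wet-bulb is the Stull single-expression approximation, clamped
to never exceed the dry-bulb and exact at saturation; it agrees with an
iterative Magnus-equation psychrometric solve to a few tenths of a degree.

What the generator does *not* reproduce — weather fronts, rain (the
published worst-case model errors occurred on rainy days with pads off),
cloud transients, multi-day autocorrelation — bounds what passing tests
show: they certify the plant/controller machinery and its qualitative
orderings under plausible diurnal forcing, not predictive accuracy against
farm data, whose minute-level records are not public.

## Numerical choices and degenerate inputs

Zero-length drivers yield empty traces; any non-finite flux or state aborts
the run naming the step. A degenerate fuzzy output (all-zero memberships)
defuzzifies to the universe midpoint with a warning. Driver CSVs are
enforced to a strict 1-minute grid, gaps linearly interpolated with a
warning. All randomness flows through explicit integer seeds; identical
inputs give bit-identical traces.

## Known limitations

* Single-node air model: no stratification or end-to-end gradients, which
  field measurements show can reach several °C.
* The summer midday regime is uncontrollable by design: with an 850 W/m²
  solar peak and a 35 °C day, the pad-cooled inlet exceeds the setpoint and
  the house rides high at the actuator ceiling regardless of controller.
* Winter heating capacity is limited to flock heat; at the minimum
  ventilation floor the house settles well below the winter setpoint under
  the synthetic −10.5 °C driver. Both saturation behaviours are exercised
  deliberately by the acceptance runs.
* Humidity and CO₂ are not modelled; the pad model is algebraic, with face
  velocity approximated by the fan-outlet velocity of each branch.
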