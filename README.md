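# coopclim

Dynamic temperature modelling and closed-loop ventilation control for
multi-tier caged layer houses operated with **combined positive- and
negative-pressure ventilation (CPNPV)** — exhaust fans pull air out of the
house while small positive-pressure fans push evaporative-pad-cooled air in,
the two flows linked by a split coefficient λ.

It is written for agricultural-engineering researchers and environmental-
control developers who want a reproducible, scriptable stand-in for a
Simulink-style henhouse climate loop: a heat-balance plant, a family of
controllers (on–off, PID, fuzzy PID, variable-universe fuzzy PID), a
synthetic minutely weather generator, and the standard control metrics.

## The model

The house air is treated as a single well-mixed node. Indoor temperature
`Ti` obeys the heat balance

```
ρ V cp · dTi/dt = Qs + Qc − Qv+ − Qvd − Qg − Qw
```

* `Qs = Ps·Sw·I` — solar gain through the envelope;
* `Qc` — sensible flock heat from the CIGR allometry
  `(6.28 m^0.75 + 25 Y)·(4·10⁻⁵(20−Ti)³ + 1)` per hen, times the sensible
  fraction `0.67(1 − 0.02(20−Ti)) − 9.8·10⁻¹¹ Ti⁶`;
* `Qv+ , Qvd` — ventilation losses of the positive-pressure and guide-plate
  branches: each draws `λL` resp. `(1−λ)L` through the cooling pad at its
  own face velocity, so its inlet temperature is
  `tc = ts + (t0 − ts)·exp(−12.28305 v^−0.30078 H)` when the pad is open
  (and the outdoor dry-bulb `t0` when closed);
* `Qg = hg·Sg·(Ti − tg)` and `Qw = ks·Fs·(tn − tw)` — floor and envelope
  exchange.

The controller measures `e = Tset − Ti` and its rate `ec`, runs a
dual-input / quad-output Mamdani fuzzy stage (49 rules, seven triangular
terms per variable) producing gain corrections ΔKP, ΔKI, ΔKD and the split
λ, and drives the exhaust flow through a discrete PID law saturated to the
seasonal actuator limits (1858–7435 m³/min). The variable-universe variant
additionally rescales the fuzzy universes every minute by
proportional-exponential factors `α = (|x|/E)^P + θ` with the adaptive
exponent `P` capped at 1.

## Worked example

```
$ coopclim synth --season summer --days 2 --seed 7 --out driver.csv
wrote 2880 rows to driver.csv
$ coopclim compare --season summer --driver driver.csv
             mae  rmse    r2  max_error  overshoot_pct  response_time_min  aoi_pct  mean_lambda
controller
onoff      3.271 4.255  None      8.781          29.96               1108     3.84            0
pid        2.923 4.037  None      8.238          29.96                NaN     2.25            0
fpid       2.489 3.469  None      7.209          26.22                NaN    2.204       0.3566
vfpid      2.493 3.464  None      7.209          26.22                NaN    2.232       0.3641
```

The two synthetic summer days span 19.3–35.0 °C outdoors with an 850 W/m²
solar peak — deliberately harsh: around midday the pad-cooled inlet air is
warmer than the 27.5 °C setpoint, so every controller saturates at the
7435 m³/min ceiling and the house rides several degrees high (the large MAE
and overshoot). The fuzzy controllers still beat on–off and plain PID on
every error measure, and their mean λ ≈ 0.36 says roughly a third of the
exhaust flow was supplied through the positive-pressure fans. `r2` is
reported as missing because the reference here is the constant setpoint.
The same comparison on a library call:

```python
from coopclim import load_preset, synth_day, simulate, evaluate_trace

bundle = load_preset("summer")
driver = synth_day(bundle.profile, seed=7, days=2, noise_sigma=0.3)
trace = simulate(driver, bundle.preset, bundle.house, controller="vfpid")
print(evaluate_trace(trace, bundle.preset))
```

## Layout

| module | contents |
| --- | --- |
| `coopclim.config` | house geometry/thermal config, seasonal presets, domain types |
| `coopclim.plant` | heat-balance fluxes, cooling pad, ventilation split, integrators |
| `coopclim.fuzzy` | Mamdani engine, 49-rule table, fuzzy PID law |
| `coopclim.variable_universe` | adaptive exponent and universe scaling factors |
| `coopclim.control` | actuator map, on–off baseline, closed-loop simulation, battery |
| `coopclim.weather` | synthetic drivers, wet-bulb psychrometrics, driver CSV I/O |
| `coopclim.metrics` | MAE/RMSE/R², oscillation index, overshoot, response time |

See `docs/methods.md` for the modelling assumptions, parameter provenance
and known limitations.
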