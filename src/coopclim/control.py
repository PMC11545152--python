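"""Closed-loop minutely simulation: controller + heat-balance plant.

Four controller variants share one loop: symmetric-hysteresis on-off,
fixed-gain PID, fuzzy PID (FPID) and variable-universe fuzzy PID (VFPID).
The controller output u is reverse-acting — a negative u means "more
cooling" — and is mapped affinely above the seasonal minimum flow, then
saturated to the seasonal actuator span (the ventilation-rate bounds
1858–7435 m3/min). The plant is advanced by explicit Euler at the driver's
1-minute cadence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import plant
from .config import ExogenousSample, HouseConfig, SeasonPreset, VentilationCommand, DEFAULT_HOUSE
from .fuzzy import FuzzyPID, FuzzyRuleTable, GainSchedule
from .variable_universe import ScalingParams

__all__ = [
    "CONTROLLER_KINDS",
    "OnOffController",
    "actuate",
    "make_controller",
    "simulate",
    "compare_controllers",
]

CONTROLLER_KINDS = ("onoff", "pid", "fpid", "vfpid")

#: (m3/min) of commanded flow per unit of controller output u. The printed
#: gains act on the SI flow scale (m3/s); this converts to actuator units.
DEFAULT_ACTUATOR_GAIN = 60.0


def actuate(u: float, preset: SeasonPreset, actuator_gain: float = DEFAULT_ACTUATOR_GAIN) -> float:
    """Map controller output u to a commanded exhaust flow, m3/min.

    Reverse-acting: cooling demand (u < 0) raises the flow above the
    seasonal minimum; the result saturates to [vent_min, vent_max].
    """
    demand = max(0.0, -actuator_gain * u)
    return min(max(preset.vent_min + demand, preset.vent_min), preset.vent_max)


@dataclass
class OnOffController:
    """Two-level thermostat with a symmetric hysteresis band.

    Commands the maximum flow above ``setpoint + hysteresis``, the minimum
    below ``setpoint - hysteresis``, and holds its previous output inside
    the band (starting at the minimum).
    """

    preset: SeasonPreset
    hysteresis: float = 0.5
    _output: Optional[float] = None

    def __post_init__(self) -> None:
        if self.hysteresis <= 0:
            raise ValueError("hysteresis must be > 0")

    def reset(self) -> None:
        self._output = None

    def step(self, ti: float) -> float:
        """Commanded flow (m3/min) for the current indoor temperature."""
        if ti > self.preset.setpoint + self.hysteresis:
            self._output = self.preset.vent_max
        elif ti < self.preset.setpoint - self.hysteresis:
            self._output = self.preset.vent_min
        elif self._output is None:
            self._output = self.preset.vent_min
        return self._output


def make_controller(
    kind: str,
    preset: SeasonPreset,
    scaling: Optional[ScalingParams] = None,
    rules: Optional[FuzzyRuleTable] = None,
    lambda_fixed: float = 0.0,
    actuator_gain: float = DEFAULT_ACTUATOR_GAIN,
    hysteresis: float = 0.5,
    zero_corrections: bool = False,
    freeze_scales: bool = False,
):
    """Build the controller object for one of the four loop variants."""
    if kind == "onoff":
        return OnOffController(preset=preset, hysteresis=hysteresis)
    if kind not in CONTROLLER_KINDS:
        raise ValueError(f"unknown controller kind {kind!r}; choose from {CONTROLLER_KINDS}")
    gains = GainSchedule(kp=preset.kp, ki=preset.ki, kd=preset.kd, season=preset.season)
    u_span = (preset.vent_max - preset.vent_min) / actuator_gain
    return FuzzyPID(
        gains=gains,
        rules=rules,
        scaling=scaling or ScalingParams(),
        fuzzy_enabled=kind in ("fpid", "vfpid"),
        adapt_universe=kind == "vfpid",
        zero_corrections=zero_corrections,
        freeze_scales=freeze_scales,
        lambda_default=lambda_fixed,
        u_span=u_span,
    )


_TRACE_COLUMNS = [
    "time_s", "ti", "tset", "e", "u", "l_neg", "lam",
    "kp", "ki", "kd", "qs", "qc", "qv_pos", "qv_duct", "qg", "qw", "net",
]


def simulate(
    driver: pd.DataFrame,
    preset: SeasonPreset,
    house: HouseConfig = DEFAULT_HOUSE,
    controller: str | object = "vfpid",
    dt: float = 60.0,
    ti0: Optional[float] = None,
    lambda_fixed: float = 0.0,
    actuator_gain: float = DEFAULT_ACTUATOR_GAIN,
    hysteresis: float = 0.5,
    scaling: Optional[ScalingParams] = None,
    rules: Optional[FuzzyRuleTable] = None,
    zero_corrections: bool = False,
    freeze_scales: bool = False,
) -> pd.DataFrame:
    """Run one closed-loop simulation over a minutely driver.

    ``controller`` is a kind name from ``CONTROLLER_KINDS`` or a pre-built
    controller object. ``ti0`` defaults to the seasonal setpoint. The trace
    records, per minute, the indoor temperature seen by the controller, the
    commanded flow (m3/min), the ventilation split and every heat flux (W).
    The run is deterministic given the driver, preset and configuration.
    """
    if isinstance(controller, str):
        ctrl = make_controller(
            controller, preset, scaling=scaling, rules=rules,
            lambda_fixed=lambda_fixed, actuator_gain=actuator_gain,
            hysteresis=hysteresis, zero_corrections=zero_corrections,
            freeze_scales=freeze_scales,
        )
        kind = controller
    else:
        ctrl = controller
        kind = "onoff" if isinstance(ctrl, OnOffController) else "custom"

    ti = preset.setpoint if ti0 is None else ti0
    rows = []
    for rec in driver.itertuples(index=False):
        if isinstance(ctrl, OnOffController):
            l_m3min = ctrl.step(ti)
            u = math.nan
            lam = lambda_fixed
        else:
            u, lam = ctrl.step(preset.setpoint, ti, dt)
            l_m3min = actuate(u, preset, actuator_gain)
        tn = getattr(rec, "tn", math.nan)
        tw = getattr(rec, "tw", math.nan)
        exo = ExogenousSample(
            time=float(rec.time_s),
            t0=float(rec.t0),
            ts=float(min(rec.ts, rec.t0)),
            irradiance=float(rec.irradiance),
            floor_temp=float(rec.tg),
            wall_inner=None if (tn is None or (isinstance(tn, float) and math.isnan(tn))) else float(tn),
            wall_outer=None if (tw is None or (isinstance(tw, float) and math.isnan(tw))) else float(tw),
            pad_open=bool(rec.pad_open),
        )
        cmd = VentilationCommand(flow=l_m3min / 60.0, split=lam)
        budget = plant.heat_budget(ti, cmd, house, exo)
        net = budget.net
        if not math.isfinite(net):
            raise plant.IntegrationError(
                f"non-finite heat budget at t={rec.time_s:.0f}s: {budget}"
            )
        if isinstance(ctrl, OnOffController):
            kp = ki = kd = math.nan
        else:
            kp, ki, kd = ctrl.state.last_gains
        rows.append(
            (
                float(rec.time_s), ti, preset.setpoint, preset.setpoint - ti,
                u, l_m3min, lam, kp, ki, kd,
                budget.qs, budget.qc, budget.qv_pos, budget.qv_duct,
                budget.qg, budget.qw, net,
            )
        )
        ti = ti + dt * net / house.thermal_capacity
        if not math.isfinite(ti):
            raise plant.IntegrationError(f"temperature diverged at t={rec.time_s:.0f}s")
    trace = pd.DataFrame(rows, columns=_TRACE_COLUMNS)
    trace.attrs["controller"] = kind
    trace.attrs["season"] = preset.season
    return trace


def controller_battery(
    base_profile,
    preset: SeasonPreset,
    house: HouseConfig = DEFAULT_HOUSE,
    n_days: int = 10,
    base_seed: int = 0,
    kinds: tuple[str, ...] = CONTROLLER_KINDS,
    noise_sigma: float = 0.3,
) -> pd.DataFrame:
    """Standardized multi-day controller comparison.

    Simulates ``n_days`` independent synthetic study days — cycling through
    the season's published per-day temperature statistics, each day with its
    own seed ``base_seed + k`` — runs every controller variant on each day,
    and returns the battery-mean metrics per controller.
    """
    from .metrics import evaluate_trace
    from .weather import season_days, synth_day

    days = season_days(base_profile)
    total: Optional[pd.DataFrame] = None
    for k in range(n_days):
        profile = days[k % len(days)]
        driver = synth_day(
            profile, seed=base_seed + k, days=1,
            noise_sigma=noise_sigma, pad_open=preset.pad_open,
        )
        rows = []
        for kind in kinds:
            trace = simulate(driver, preset, house, controller=kind)
            rows.append({"controller": kind, **evaluate_trace(trace, preset).as_dict()})
        table = pd.DataFrame(rows).set_index("controller").drop(columns=["r2", "response_time_min"])
        total = table if total is None else total + table
    assert total is not None
    return total / n_days


def compare_controllers(
    driver: pd.DataFrame,
    preset: SeasonPreset,
    house: HouseConfig = DEFAULT_HOUSE,
    kinds: tuple[str, ...] = CONTROLLER_KINDS,
    **kwargs,
) -> pd.DataFrame:
    """Run every controller variant on one driver; one metrics row each."""
    from .metrics import evaluate_trace

    rows = []
    for kind in kinds:
        trace = simulate(driver, preset, house, controller=kind, **kwargs)
        report = evaluate_trace(trace, preset)
        rows.append({"controller": kind, **report.as_dict()})
    return pd.DataFrame(rows).set_index("controller")
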