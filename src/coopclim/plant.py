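"""Heat-balance plant model of the layer house.

The indoor air is treated as well mixed with a single temperature state Ti.
Its heat budget sums solar gain through the envelope, sensible heat from the
flock (CIGR form), ventilation losses through the combined positive- and
negative-pressure paths (both drawing through the evaporative cooling pad
when it is open), convective exchange with the floor/manure pit, and
conduction through the envelope:

    rho*V*cp * dTi/dt = Qs + Qc - Qv+ - Qvd - Qg - Qw

Lighting/equipment gains and infiltration losses are neglected. Time is
advanced by explicit Euler at the 1-minute data cadence by default; a
classical fourth-order stepper is available for convergence checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import ExogenousSample, HouseConfig, VentilationCommand

__all__ = [
    "HeatBudget",
    "HouseState",
    "IntegrationError",
    "solar_gain",
    "total_heat_production",
    "sensible_heat",
    "pad_outlet_temperature",
    "split_velocities",
    "ventilation_heat_loss",
    "floor_heat_loss",
    "envelope_heat_loss",
    "heat_budget",
    "temperature_derivative",
    "step",
]

#: below this pad face velocity (m/s) the air is assumed fully saturated
#: (outlet at wet-bulb); the associated mass flow is then ~0 anyway.
VELOCITY_FLOOR = 1e-6


class IntegrationError(RuntimeError):
    """Raised when a time step produces a non-finite temperature or flux."""


@dataclass(frozen=True)
class HouseState:
    """Indoor temperature state, degC."""

    ti: float


@dataclass(frozen=True)
class HeatBudget:
    """All heat fluxes of one instant, W. ``net`` is gains minus losses."""

    qs: float  # solar gain
    qc: float  # flock sensible heat
    qv_pos: float  # ventilation loss, positive-pressure branch
    qv_duct: float  # ventilation loss, guide-plate branch
    qg: float  # floor loss
    qw: float  # envelope loss

    @property
    def net(self) -> float:
        return self.qs + self.qc - (self.qv_pos + self.qv_duct) - self.qg - self.qw


def solar_gain(ps: float, sw: float, irradiance: float) -> float:
    """Solar heat gain Qs = Ps*Sw*I, W."""
    if irradiance < 0:
        raise ValueError("irradiance must be >= 0")
    if not 0.0 <= ps <= 1.0:
        raise ValueError("radiation coefficient must lie in [0, 1]")
    if sw <= 0:
        raise ValueError("solar area must be > 0")
    return ps * sw * irradiance


def total_heat_production(m: float, y: float, ti: float) -> float:
    """Total metabolic heat of the flock (CIGR form), W.

    Qt = (6.28*M^0.75 + 25*Y) * (4e-5*(20 - Ti)^3 + 1) with M the total
    flock weight (kg) and Y daily egg production (kg/day). The cubic term is
    the thermoregulatory correction, exactly 1 at Ti = 20 degC.
    """
    if m < 0 or y < 0:
        raise ValueError("flock mass and egg yield must be >= 0")
    return (6.28 * m**0.75 + 25.0 * y) * (4e-5 * (20.0 - ti) ** 3 + 1.0)


def sensible_fraction(ti: float) -> float:
    """Sensible share of total flock heat; clamped to [0, 1] at extremes."""
    frac = 0.67 * (1.0 - 0.02 * (20.0 - ti)) - 9.8e-11 * ti**6
    return min(max(frac, 0.0), 1.0)


def sensible_heat(m: float, y: float, ti: float) -> float:
    """Sensible heat released by the flock to room air, Qc, W."""
    return total_heat_production(m, y, ti) * sensible_fraction(ti)


def pad_outlet_temperature(
    t0: float,
    ts: float,
    v: float,
    thickness: float,
    rho: float = 1.2,
    cp: float = 1006.0,
    pad_open: bool = True,
    exponent_literal: bool = False,
) -> float:
    """Air temperature after the evaporative cooling pad, degC.

    With the pad open the outlet approaches the outdoor wet-bulb ts as the
    residual fraction E = exp(-12.28305 * v^-0.30078 * H) of the wet-bulb
    depression survives:  tc = ts + (t0 - ts)*E, always within [ts, t0].
    At vanishing face velocity the air saturates completely (tc -> ts).
    With the pad closed the outlet is simply the outdoor dry-bulb t0.
    """
    if ts > t0:
        raise ValueError("wet-bulb must not exceed dry-bulb")
    if v < 0:
        raise ValueError("velocity must be >= 0")
    if thickness <= 0:
        raise ValueError("pad thickness must be > 0")
    if not pad_open:
        return t0
    if t0 == ts:
        return t0
    if v < VELOCITY_FLOOR:
        return ts
    exponent = -12.28305 * v**-0.30078 * thickness
    if exponent_literal:
        exponent *= rho * cp
    decay = math.exp(exponent)
    return ts + (t0 - ts) * decay


def split_velocities(
    l_neg: float, split: float, a_pos: float, a_duct: float
) -> tuple[float, float]:
    """Face velocities (m/s) of the two inlet branches.

    v+ = lambda*L-/A+ through the positive-pressure fans and
    vd = (1-lambda)*L-/Ad through the guide plates; together they conserve
    the exhaust flow: A+*v+ + Ad*vd = L-.
    """
    if l_neg < 0:
        raise ValueError("flow must be >= 0")
    if not 0.0 <= split <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if a_pos <= 0 or a_duct <= 0:
        raise ValueError("areas must be > 0")
    return split * l_neg / a_pos, (1.0 - split) * l_neg / a_duct


def ventilation_heat_loss(
    ti: float,
    cmd: VentilationCommand,
    cfg: HouseConfig,
    exo: ExogenousSample,
) -> tuple[float, float]:
    """Heat removed by the two ventilation branches (Qv+, Qvd), W.

    Each branch draws its own face velocity through the pad, hence its own
    pad-outlet temperature; its mass flow is rho times its volume flow.
    """
    v_pos, v_duct = split_velocities(cmd.flow, cmd.split, cfg.pos_fan_area, cfg.duct_area)
    tc_pos = pad_outlet_temperature(
        exo.t0, exo.ts, v_pos, cfg.pad_thickness, cfg.air_density, cfg.air_cp,
        pad_open=exo.pad_open, exponent_literal=cfg.pad_exponent_literal,
    )
    tc_duct = pad_outlet_temperature(
        exo.t0, exo.ts, v_duct, cfg.pad_thickness, cfg.air_density, cfg.air_cp,
        pad_open=exo.pad_open, exponent_literal=cfg.pad_exponent_literal,
    )
    m_pos = cfg.air_density * cmd.split * cmd.flow
    m_duct = cfg.air_density * (1.0 - cmd.split) * cmd.flow
    return m_pos * cfg.air_cp * (ti - tc_pos), m_duct * cfg.air_cp * (ti - tc_duct)


def floor_heat_loss(ti: float, tg: float, hg: float, sg: float) -> float:
    """Convective floor exchange Qg = hg*Sg*(Ti - tg), W (negative = gain)."""
    if sg <= 0:
        raise ValueError("floor area must be > 0")
    return hg * sg * (ti - tg)


def envelope_heat_loss(tn: float, tw: float, ks: float, fs: float) -> float:
    """Envelope conduction Qw = ks*Fs*(tn - tw), W."""
    if fs <= 0:
        raise ValueError("envelope area must be > 0")
    return ks * fs * (tn - tw)


def heat_budget(
    ti: float,
    cmd: VentilationCommand,
    cfg: HouseConfig,
    exo: ExogenousSample,
) -> HeatBudget:
    """Assemble every flux of the heat balance at temperature ``ti``.

    Missing wall temperatures are substituted per the synthetic-mode rule:
    inner surface from the current indoor temperature, outer surface from
    the outdoor dry-bulb.
    """
    tn = exo.wall_inner if exo.wall_inner is not None else ti
    tw = exo.wall_outer if exo.wall_outer is not None else exo.t0
    qv_pos, qv_duct = ventilation_heat_loss(ti, cmd, cfg, exo)
    # per-animal allometry summed over the flock
    n = cfg.flock_count
    qc = n * sensible_heat(cfg.flock_mass / n, cfg.egg_yield / n, ti)
    return HeatBudget(
        qs=solar_gain(cfg.radiation_coeff, cfg.solar_area, exo.irradiance),
        qc=qc,
        qv_pos=qv_pos,
        qv_duct=qv_duct,
        qg=floor_heat_loss(ti, exo.floor_temp, cfg.floor_htc, cfg.floor_area),
        qw=envelope_heat_loss(tn, tw, cfg.envelope_htc, cfg.envelope_area),
    )


def temperature_derivative(budget: HeatBudget, cfg: HouseConfig) -> float:
    """dTi/dt = net / (rho*V*cp), degC/s."""
    return budget.net / cfg.thermal_capacity


def _check_budget(budget: HeatBudget, when: str) -> None:
    for name in ("qs", "qc", "qv_pos", "qv_duct", "qg", "qw"):
        if not math.isfinite(getattr(budget, name)):
            raise IntegrationError(f"non-finite flux {name} {when}")


def step(
    state: HouseState,
    exo: ExogenousSample,
    cmd: VentilationCommand,
    cfg: HouseConfig,
    dt: float = 60.0,
    method: str = "euler",
) -> HouseState:
    """Advance the indoor temperature by one time step of ``dt`` seconds.

    ``method`` is "euler" (default, matching the 1-min data cadence) or
    "rk4" for the classical fourth-order scheme used in convergence tests.
    Exogenous inputs and the ventilation command are held over the step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")

    def deriv(ti: float) -> float:
        budget = heat_budget(ti, cmd, cfg, exo)
        _check_budget(budget, f"at Ti={ti:.3f}")
        return temperature_derivative(budget, cfg)

    if method == "euler":
        ti_new = state.ti + dt * deriv(state.ti)
    elif method == "rk4":
        k1 = deriv(state.ti)
        k2 = deriv(state.ti + 0.5 * dt * k1)
        k3 = deriv(state.ti + 0.5 * dt * k2)
        k4 = deriv(state.ti + dt * k3)
        ti_new = state.ti + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    else:
        raise ValueError(f"unknown integrator {method!r}")
    if not math.isfinite(ti_new):
        raise IntegrationError("temperature became non-finite after step")
    return HouseState(ti=ti_new)
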