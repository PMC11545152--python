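"""House geometry, thermal parameters, seasonal control presets and their YAML I/O.

The default numbers describe a 100 m x 15 m x 4 m multi-tier cage house for
48,000 white-feather layers ventilated by 18 exhaust (negative-pressure) fans,
95 small positive-pressure inlet fans and 15 cm evaporative cooling pads.
All internal units are SI (m, s, W, kg); ventilation appears in m3/min only at
the config/CLI boundary, converted explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

try:  # py>=3.9
    from importlib import resources
except ImportError:  # pragma: no cover
    import importlib_resources as resources  # type: ignore

__all__ = [
    "HouseConfig",
    "SeasonPreset",
    "DayProfile",
    "ExogenousSample",
    "VentilationCommand",
    "PresetBundle",
    "DEFAULT_HOUSE",
    "load_preset",
    "preset_names",
]


@dataclass(frozen=True)
class HouseConfig:
    """Geometry, thermal coefficients and flock state of the layer house.

    Parameters
    ----------
    volume : float
        Interior air volume V, m3.
    floor_area : float
        Indoor floor (manure-pit) surface area Sg, m2.
    envelope_area : float
        Envelope (perimeter wall) surface area Fs, m2.
    solar_area : float
        Effective area receiving solar radiation Sw, m2.
    pos_fan_area : float
        Summed outlet area of all positive-pressure fans A+, m2.
    duct_area : float
        Summed cross-section of all guide-plate (duct) inlets Ad, m2.
    pad_thickness : float
        Evaporative cooling pad thickness H, m.
    radiation_coeff : float
        Dimensionless radiation conversion coefficient Ps of the envelope.
    floor_htc : float
        Floor-air convective heat transfer coefficient hg, W/(m2 degC).
    envelope_htc : float
        Envelope heat transfer coefficient ks, W/(m2 degC).
    air_density, air_cp : float
        Moist-air density (kg/m3) and specific heat (J/(kg degC)), treated
        as constants.
    flock_mass : float
        Total live weight of the flock M, kg.
    egg_yield : float
        Total daily egg production Y, kg/day.
    flock_count : int
        Number of birds. The metabolic heat law is a per-animal allometry
        (6.28*m^0.75 per hen), so the house-level budget evaluates it at the
        mean bird mass and sums over the flock; a count of 1 reproduces the
        aggregate single-animal reading.
    pad_exponent_literal : bool
        If True the pad decay exponent additionally multiplies rho*cp
        (an alternative typographic reading; drives the pad to an all-or-
        nothing cooler and is off by default).
    roof_htc, insulation_htc, pad_area : float
        Carried for completeness (roof heat exchange, insulation board,
        total pad area); not used by the default heat budget.
    """

    volume: float = 6375.0
    floor_area: float = 1500.0
    envelope_area: float = 920.0
    solar_area: float = 1491.0
    pos_fan_area: float = 6.7
    duct_area: float = 4.0
    pad_thickness: float = 0.15
    radiation_coeff: float = 0.64
    floor_htc: float = 6.0
    envelope_htc: float = 0.93
    air_density: float = 1.2
    air_cp: float = 1006.0
    flock_mass: float = 92900.0
    egg_yield: float = 2600.0
    flock_count: int = 48000
    pad_exponent_literal: bool = False
    roof_htc: float = 5.4
    insulation_htc: float = 0.042
    pad_area: float = 1504.0

    def __post_init__(self) -> None:
        positive = {
            "volume": self.volume,
            "floor_area": self.floor_area,
            "envelope_area": self.envelope_area,
            "solar_area": self.solar_area,
            "pos_fan_area": self.pos_fan_area,
            "duct_area": self.duct_area,
            "pad_thickness": self.pad_thickness,
            "floor_htc": self.floor_htc,
            "envelope_htc": self.envelope_htc,
            "air_density": self.air_density,
            "air_cp": self.air_cp,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.flock_mass < 0 or self.egg_yield < 0:
            raise ValueError("flock_mass and egg_yield must be >= 0")
        if self.flock_count < 1:
            raise ValueError("flock_count must be >= 1")
        if not 0.0 <= self.radiation_coeff <= 1.0:
            raise ValueError("radiation_coeff must lie in [0, 1]")

    @property
    def thermal_capacity(self) -> float:
        """rho*V*cp, J/degC — heat capacity of the indoor air mass."""
        return self.air_density * self.volume * self.air_cp


DEFAULT_HOUSE = HouseConfig()


@dataclass(frozen=True)
class SeasonPreset:
    """Seasonal setpoint, base PID gains, actuator limits and pad state."""

    season: str
    setpoint: float  # degC
    kp: float
    ki: float
    kd: float
    vent_min: float = 1858.0  # m3/min
    vent_max: float = 7435.0  # m3/min
    pad_open: bool = False

    def __post_init__(self) -> None:
        if not (self.kp > 0 and self.ki > 0 and self.kd > 0):
            raise ValueError("PID gains must be > 0")
        if not self.vent_min < self.vent_max:
            raise ValueError("vent_min must be < vent_max")


@dataclass(frozen=True)
class DayProfile:
    """Daily statistics the synthetic weather generator reproduces."""

    t_min: float  # degC, diurnal minimum (near 05:00)
    t_max: float  # degC, diurnal maximum (near 15:00)
    rh_mean: float  # %, daily mean relative humidity
    irradiance_peak: float  # W/m2, solar noon peak
    sunrise_h: float = 6.0  # hour of day
    sunset_h: float = 18.0
    floor_offset: float = 0.0  # tg = daily-mean outdoor T + offset, degC
    season: str = "summer"
    t_mean: Optional[float] = None  # degC; skews the cooling branch so the
    # noise-free daily mean matches this anchor (None = symmetric curve)

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be < t_max")
        if self.t_mean is not None and not self.t_min < self.t_mean < self.t_max:
            raise ValueError("t_mean must lie strictly between t_min and t_max")
        if not 0.0 < self.rh_mean < 100.0:
            raise ValueError("rh_mean must lie in (0, 100)")
        if self.irradiance_peak < 0:
            raise ValueError("irradiance_peak must be >= 0")
        if not self.sunrise_h < self.sunset_h:
            raise ValueError("sunrise must precede sunset")


@dataclass(frozen=True)
class ExogenousSample:
    """One timestamped record of outdoor / boundary conditions.

    ``wall_inner`` / ``wall_outer`` may be None, in which case the simulation
    substitutes the previous indoor temperature and the outdoor dry-bulb
    respectively (measured values override when a CSV supplies them).
    """

    time: float  # s since simulation start
    t0: float  # outdoor dry-bulb, degC
    ts: float  # outdoor wet-bulb, degC
    irradiance: float  # W/m2
    floor_temp: float  # manure-pit / floor temperature tg, degC
    wall_inner: Optional[float] = None  # tn, degC
    wall_outer: Optional[float] = None  # tw, degC
    pad_open: bool = False

    def __post_init__(self) -> None:
        if self.ts > self.t0 + 1e-9:
            raise ValueError(f"wet-bulb ts={self.ts} exceeds dry-bulb t0={self.t0}")
        if self.irradiance < 0:
            raise ValueError("irradiance must be >= 0")


@dataclass(frozen=True)
class VentilationCommand:
    """Total negative-pressure exhaust flow and the positive-pressure split.

    ``flow`` is the total exhaust flow L- in m3/s; ``split`` is the coupling
    coefficient lambda in [0, 1]: the positive-pressure fans supply
    lambda*L- and the guide plates the remaining (1-lambda)*L-.
    """

    flow: float  # m3/s
    split: float  # dimensionless

    def __post_init__(self) -> None:
        if self.flow < 0:
            raise ValueError("flow must be >= 0")
        if not 0.0 <= self.split <= 1.0:
            raise ValueError("split (lambda) must lie in [0, 1]")


@dataclass(frozen=True)
class PresetBundle:
    preset: SeasonPreset
    house: HouseConfig
    profile: DayProfile


_PRESET_DIR = "data/presets"


def preset_names() -> list[str]:
    root = resources.files("coopclim").joinpath(_PRESET_DIR)
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name_or_path: str | Path) -> PresetBundle:
    """Load a seasonal preset from a shipped name or a YAML file path."""
    path = Path(name_or_path)
    if path.suffix in {".yaml", ".yml"} and path.exists():
        text = path.read_text()
    else:
        res = resources.files("coopclim").joinpath(f"{_PRESET_DIR}/{name_or_path}.yaml")
        try:
            text = res.read_text()
        except FileNotFoundError:
            raise FileNotFoundError(
                f"unknown preset {name_or_path!r}; shipped presets: {preset_names()}"
            ) from None
    raw = yaml.safe_load(text)
    gains = raw.get("gains", {})
    vent = raw.get("ventilation", {})
    preset = SeasonPreset(
        season=raw["season"],
        setpoint=float(raw["setpoint_c"]),
        kp=float(gains["kp"]),
        ki=float(gains["ki"]),
        kd=float(gains["kd"]),
        vent_min=float(vent.get("min_m3_per_min", 1858.0)),
        vent_max=float(vent.get("max_m3_per_min", 7435.0)),
        pad_open=bool(raw.get("pad_open", False)),
    )
    house_raw = raw.get("house", {}) or {}
    field_names = {f.name for f in dataclasses.fields(HouseConfig)}
    unknown = set(house_raw) - field_names
    if unknown:
        raise ValueError(f"unknown house keys in preset: {sorted(unknown)}")
    house = HouseConfig(**house_raw)
    prof_raw = raw.get("profile", {}) or {}
    profile = DayProfile(season=raw["season"], **prof_raw)
    return PresetBundle(preset=preset, house=house, profile=profile)
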