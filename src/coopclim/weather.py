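"""Synthetic minutely weather drivers and driver-CSV I/O.

Real minute-level farm drivers are not published, so the generator emulates
the documented seasonal day statistics: the outdoor dry-bulb follows a
smooth diurnal curve anchored exactly at the daily minimum (05:00) and
maximum (15:00), irradiance is a half-sine between sunrise and sunset,
relative humidity is anti-correlated with temperature, and a seeded AR(1)
process adds minute-scale weather noise. The wet-bulb temperature is
derived psychrometrically from dry-bulb and humidity.

Driver CSV dialect: columns
``timestamp,t0,ts,rh,irradiance,tg,tn,tw,pad_open`` at a strict 1-minute
cadence; ``tn``/``tw`` may be empty (the simulation then substitutes its
synthetic-mode defaults).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import DayProfile

__all__ = [
    "wet_bulb",
    "synth_day",
    "season_days",
    "interpolate_minutely",
    "read_driver",
    "write_driver",
]

#: Published per-day outdoor statistics of the monitored seasons:
#: (t_min degC, t_max degC, daily mean degC, mean RH %). The battery of
#: synthetic study days cycles through these.
SEASON_DAY_STATS: dict[str, tuple[tuple[float, float, float, float], ...]] = {
    "summer": (
        (14.2, 29.1, 22.3, 48.2),
        (17.4, 25.6, 21.7, 47.1),
        (15.9, 31.1, 24.2, 54.6),
        (18.5, 32.2, 26.3, 41.6),
        (19.3, 35.0, 26.9, 45.4),
    ),
    "autumn": (
        (16.5, 25.5, 20.9, 38.0),
        (13.2, 27.4, 19.4, 45.3),
        (16.6, 26.9, 20.1, 43.9),
        (14.2, 22.1, 18.1, 34.5),
        (12.2, 24.3, 15.1, 35.2),
    ),
    "winter": (
        (-10.5, 1.4, -5.7, 46.9),
        (-8.4, 2.8, -3.8, 46.5),
        (-4.5, 7.7, 0.8, 44.3),
        (-2.4, 8.7, 1.9, 44.6),
        (-0.3, 8.2, 2.7, 43.4),
    ),
}


def season_days(base: DayProfile) -> tuple[DayProfile, ...]:
    """Per-day profiles of one season: the base profile's solar/floor
    settings combined with each published day's temperature statistics."""
    import dataclasses

    stats = SEASON_DAY_STATS[base.season]
    return tuple(
        dataclasses.replace(base, t_min=lo, t_max=hi, t_mean=mean, rh_mean=rh)
        for lo, hi, mean, rh in stats
    )

DRIVER_COLUMNS = ["t0", "ts", "rh", "irradiance", "tg", "tn", "tw", "pad_open"]

_T_MIN_HOUR = 5.0
_T_MAX_HOUR = 15.0


def wet_bulb(t0, rh):
    """Wet-bulb temperature (degC) from dry-bulb and relative humidity (%).

    Single-expression psychrometric approximation (Stull 2011 form),
    clamped so the wet bulb never exceeds the dry bulb; at saturation
    (rh = 100 %) the two coincide exactly. Accepts scalars or arrays.
    """
    t = np.asarray(t0, dtype=float)
    h = np.asarray(rh, dtype=float)
    if np.any(h <= 0) or np.any(h > 100):
        raise ValueError("relative humidity must lie in (0, 100]")
    tw = (
        t * np.arctan(0.151977 * np.sqrt(h + 8.313659))
        + np.arctan(t + h)
        - np.arctan(h - 1.676331)
        + 0.00391838 * h**1.5 * np.arctan(0.023101 * h)
        - 4.686035
    )
    tw = np.minimum(tw, t)
    tw = np.where(h >= 100.0, t, tw)
    if np.isscalar(t0) and np.isscalar(rh):
        return float(tw)
    return tw


def _fall_mean(gamma: float) -> float:
    """Mean of the cooling-branch shape ((1+cos(pi*s))/2)^gamma over s in [0,1]."""
    s = np.linspace(0.0, 1.0, 1001)
    return float(np.trapezoid((0.5 + 0.5 * np.cos(np.pi * s)) ** gamma, s))


def _solve_gamma(t_min: float, t_max: float, t_mean: float) -> float:
    """Cooling-branch skew exponent reproducing the daily mean anchor.

    The warming branch (05:00-15:00) is a fixed half-cosine with mean
    amplitude 1/2; the exponent gamma of the cooling branch is found by
    bisection so the 24-h mean of the noise-free curve equals ``t_mean``.
    Clamped to [0.3, 6]: anchors outside the reachable range get the
    closest attainable mean.
    """
    amp = t_max - t_min
    rise_len = _T_MAX_HOUR - _T_MIN_HOUR
    fall_len = 24.0 - rise_len
    target = ((t_mean - t_min) / amp * 24.0 - rise_len * 0.5) / fall_len
    lo, hi = 0.3, 6.0
    if target >= _fall_mean(lo):
        return lo
    if target <= _fall_mean(hi):
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _fall_mean(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _diurnal_curve(
    hours: np.ndarray, t_min: float, t_max: float, gamma: float = 1.0
) -> np.ndarray:
    """Diurnal curve hitting t_min at 05:00 and t_max at 15:00 exactly.

    Half-cosine warming branch; cooling branch is the half-cosine raised to
    ``gamma`` (gamma > 1 drops faster after the peak, pulling the daily mean
    below the min/max midpoint as observed on clear winter days).
    """
    h = np.mod(hours - _T_MIN_HOUR, 24.0)  # 0 at the minimum
    rise_len = _T_MAX_HOUR - _T_MIN_HOUR  # 10 h warming
    fall_len = 24.0 - rise_len  # 14 h cooling
    amp = t_max - t_min
    rising = h <= rise_len
    out = np.empty_like(h)
    out[rising] = t_min + amp * 0.5 * (1.0 - np.cos(np.pi * h[rising] / rise_len))
    shape = 0.5 * (1.0 + np.cos(np.pi * (h[~rising] - rise_len) / fall_len))
    out[~rising] = t_min + amp * shape**gamma
    return out


def _ar1(n: int, sigma: float, rng: np.random.Generator, phi: float = 0.95) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sigma``."""
    if sigma == 0.0:
        return np.zeros(n)
    eps = rng.standard_normal(n) * sigma * math.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.standard_normal() * sigma
    for k in range(1, n):
        x[k] = phi * x[k - 1] + eps[k]
    return x


def synth_day(
    profile: DayProfile,
    seed: int = 0,
    days: int = 1,
    noise_sigma: float = 0.3,
    pad_open: Optional[bool] = None,
    dt_s: float = 60.0,
) -> pd.DataFrame:
    """Generate a minutely exogenous driver of ``days`` diurnal cycles.

    With ``noise_sigma=0`` the dry-bulb hits the profile's t_min/t_max
    exactly. ``pad_open`` defaults to open in summer, closed otherwise.
    Returns a DataFrame with a ``time_s`` column and the driver columns.
    """
    if days < 0:
        raise ValueError("days must be >= 0")
    n = int(round(days * 86400.0 / dt_s))
    rng = np.random.default_rng(seed)
    time_s = np.arange(n) * dt_s
    hours = time_s / 3600.0

    gamma = 1.0
    if profile.t_mean is not None:
        gamma = _solve_gamma(profile.t_min, profile.t_max, profile.t_mean)
    base = _diurnal_curve(hours, profile.t_min, profile.t_max, gamma)
    t0 = base + _ar1(n, noise_sigma, rng)

    base_mean = 0.5 * (profile.t_min + profile.t_max)
    rh = profile.rh_mean - 1.5 * (t0 - base_mean) + _ar1(n, noise_sigma * 2.0, rng)
    rh = np.clip(rh, 5.0, 98.0)
    ts = np.minimum(wet_bulb(t0, rh), t0)

    day_frac = np.mod(hours, 24.0)
    daylight = (day_frac >= profile.sunrise_h) & (day_frac <= profile.sunset_h)
    irr = np.zeros(n)
    span = profile.sunset_h - profile.sunrise_h
    irr[daylight] = profile.irradiance_peak * np.sin(
        np.pi * (day_frac[daylight] - profile.sunrise_h) / span
    )
    irr = np.clip(irr, 0.0, None)

    # manure-pit temperature: daily mean of the noise-free curve plus offset
    base_daily_mean = float(
        _diurnal_curve(np.arange(1440) / 60.0, profile.t_min, profile.t_max, gamma).mean()
    )
    tg = np.full(n, base_daily_mean + profile.floor_offset)

    if pad_open is None:
        pad_open = profile.season == "summer"

    return pd.DataFrame(
        {
            "time_s": time_s,
            "t0": t0,
            "ts": ts,
            "rh": rh,
            "irradiance": irr,
            "tg": tg,
            "tn": np.nan,
            "tw": np.nan,
            "pad_open": bool(pad_open),
        }
    )


def interpolate_minutely(series: pd.Series) -> pd.Series:
    """Resample a sparsely sampled time series to a strict 1-min cadence.

    ``series`` must carry a DatetimeIndex with strictly increasing, unique
    timestamps; values at the input timestamps are reproduced exactly and
    gaps are filled by linear interpolation in time.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must be indexed by timestamps")
    if series.index.has_duplicates:
        raise ValueError("duplicate timestamps")
    if not series.index.is_monotonic_increasing:
        raise ValueError("timestamps must be strictly increasing")
    out = series.resample("1min").asfreq()
    # keep original (possibly off-grid) points while interpolating
    out = pd.concat([out, series]).sort_index()
    out = out[~out.index.duplicated(keep="last")]
    out = out.interpolate(method="time")
    return out.resample("1min").asfreq().interpolate(method="time")


def read_driver(path: str | Path) -> pd.DataFrame:
    """Read a driver CSV, enforce the 1-min cadence and fill gaps.

    Gaps in the minute grid are filled by linear interpolation with a
    warning; ``tn``/``tw`` stay NaN where absent.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in ("t0", "ts", "irradiance", "tg", "pad_open") if c not in df.columns]
    if missing:
        raise ValueError(f"driver CSV missing columns: {missing}")
    df = df.set_index("timestamp").sort_index()
    full = pd.date_range(df.index[0], df.index[-1], freq="1min")
    if len(full) != len(df):
        import warnings

        warnings.warn(
            f"driver has {len(full) - len(df)} gap(s) on the 1-min grid; "
            "filling by linear interpolation",
            stacklevel=2,
        )
        df = df.reindex(full)
        num_cols = [c for c in df.columns if c != "pad_open"]
        df[num_cols] = df[num_cols].interpolate(method="time")
        df["pad_open"] = df["pad_open"].astype("boolean").ffill().astype(bool)
    df = df.reset_index(names="timestamp")
    df["time_s"] = (df["timestamp"] - df["timestamp"].iloc[0]).dt.total_seconds()
    df["pad_open"] = df["pad_open"].astype(bool)
    for col in ("tn", "tw"):
        if col not in df.columns:
            df[col] = np.nan
    return df


def write_driver(df: pd.DataFrame, path: str | Path, start: str = "2023-06-05") -> None:
    """Write a driver DataFrame in the standard CSV dialect."""
    out = df.copy()
    if "timestamp" not in out.columns:
        t0 = pd.Timestamp(start)
        out.insert(0, "timestamp", t0 + pd.to_timedelta(out["time_s"], unit="s"))
    cols = ["timestamp"] + [c for c in DRIVER_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)
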