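"""Closed-loop evaluation statistics.

Accuracy of a simulated series against a reference (MAE, RMSE, R2, maximum
error), the mean oscillation index

    dAoi = 1/(K-1) * sum_{t=2..K} |T(t) - T(t-1)| / T_av * 100 %,

which normalises the average step-to-step temperature change by the series
mean (lower = steadier control), and setpoint-tracking metrics (overshoot
as a percentage of the setpoint, settling-style response time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SeasonPreset

__all__ = [
    "MetricsReport",
    "basic_errors",
    "oscillation_index",
    "control_metrics",
    "improvement_pct",
    "evaluate_trace",
]


@dataclass(frozen=True)
class MetricsReport:
    mae: float  # degC
    rmse: float  # degC
    r2: Optional[float]
    max_error: float  # degC
    overshoot_pct: float  # % of setpoint
    response_time: Optional[float]  # min
    aoi: float  # % mean oscillation index
    mean_lambda: float = math.nan

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "max_error": self.max_error,
            "overshoot_pct": self.overshoot_pct,
            "response_time_min": self.response_time,
            "aoi_pct": self.aoi,
            "mean_lambda": self.mean_lambda,
        }


def basic_errors(
    sim: Sequence[float], ref: Sequence[float]
) -> tuple[float, float, Optional[float], float]:
    """(MAE, RMSE, R2, max |error|) of a simulated series vs a reference.

    R2 is the coefficient of determination about the reference mean; it is
    undefined (None) for a constant reference.
    """
    s = np.asarray(sim, dtype=float)
    r = np.asarray(ref, dtype=float)
    if s.shape != r.shape:
        raise ValueError("series must have equal length")
    if s.size < 2:
        raise ValueError("need at least 2 points")
    d = s - r
    mae = float(np.mean(np.abs(d)))
    rmse = float(np.sqrt(np.mean(d * d)))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = None if ss_tot == 0.0 else float(1.0 - np.sum(d * d) / ss_tot)
    return mae, rmse, r2, float(np.max(np.abs(d)))


def oscillation_index(temps: Sequence[float]) -> float:
    """Mean oscillation index dAoi, %."""
    t = np.asarray(temps, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points")
    t_av = float(t.mean())
    if t_av == 0.0:
        raise ValueError("mean temperature is zero; index undefined")
    return float(np.mean(np.abs(np.diff(t))) / t_av * 100.0)


def control_metrics(
    temps: Sequence[float],
    setpoint: float,
    dt_min: float = 1.0,
    band: float = 0.1,
) -> tuple[float, Optional[float]]:
    """(overshoot %, response time min) of a setpoint-tracking trace.

    Overshoot is the peak excursion above the setpoint as a percentage of
    the setpoint, clipped at 0. Response time is measured from the largest
    disturbance (maximum |error|) to the first instant after which the
    trace stays within +-``band`` degC of the setpoint; None if it never
    settles.
    """
    t = np.asarray(temps, dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    overshoot = max(0.0, (float(t.max()) - setpoint) / setpoint * 100.0)
    err = np.abs(t - setpoint)
    onset = int(np.argmax(err))
    inside = err[onset:] <= band
    # last index (relative to onset) that is still outside the band
    outside = np.nonzero(~inside)[0]
    if inside.size == 0:
        return overshoot, None
    if outside.size == 0:
        settle = 0
    elif outside[-1] == inside.size - 1:
        return overshoot, None
    else:
        settle = int(outside[-1]) + 1
    return overshoot, settle * dt_min


def improvement_pct(a: float, b: float) -> float:
    """Relative improvement of ``b`` over baseline ``a``: (a-b)/a*100 %."""
    if a <= 0:
        raise ValueError("baseline must be > 0")
    return (a - b) / a * 100.0


def evaluate_trace(trace: pd.DataFrame, preset: SeasonPreset) -> MetricsReport:
    """Full metrics report of one closed-loop trace against its setpoint."""
    ti = trace["ti"].to_numpy()
    ref = np.full_like(ti, preset.setpoint)
    d = ti - ref
    mae = float(np.mean(np.abs(d)))
    rmse = float(np.sqrt(np.mean(d * d)))
    max_err = float(np.max(np.abs(d)))
    overshoot, response = control_metrics(ti, preset.setpoint)
    return MetricsReport(
        mae=mae,
        rmse=rmse,
        r2=None,  # setpoint reference is constant
        max_error=max_err,
        overshoot_pct=overshoot,
        response_time=response,
        aoi=oscillation_index(ti),
        mean_lambda=float(trace["lam"].mean()),
    )
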