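"""Online contraction/expansion of fuzzy universes (variable-universe scaling).

The input universes for the error e and its rate ec, and the output universe,
are rescaled every control step by proportional-exponential factors

    alpha(x) = (|x|/E)^P + theta,      beta = (alpha_e + alpha_ec)/2 + theta

whose shared exponent P adapts to the operating point:

    P = E1 / (|e|*(E1+E2) + v) + E2 / (|ec|*(E1+E2) + v),   capped at 1.

Small errors therefore shrink the universes (finer rule granularity near the
setpoint) while errors at the universe edge restore them (alpha -> 1+theta).
theta keeps the universes from collapsing to zero width; v guards the
denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ScalingParams",
    "UniverseScale",
    "scaling_exponent",
    "input_scaling",
    "output_scaling",
    "compute_scale",
    "contract_universes",
]


@dataclass(frozen=True)
class ScalingParams:
    """Initial half-widths and numerical guards of the adaptive universes."""

    e_half: float = 3.0  # E1, degC
    ec_half: float = 1.5  # E2, degC per control step
    out_half: float = 5.0  # U3, controller output units
    theta: float = 1e-4  # scaling-factor floor
    v: float = 1e-6  # denominator guard

    def __post_init__(self) -> None:
        if not (self.e_half > 0 and self.ec_half > 0 and self.out_half > 0):
            raise ValueError("universe half-widths must be > 0")
        if not (0 < self.theta < 1 and 0 < self.v < 1):
            raise ValueError("theta and v must be small positive numbers")


@dataclass(frozen=True)
class UniverseScale:
    """Scaling factors of one control step."""

    alpha_e: float
    alpha_ec: float
    beta: float
    p: float


def scaling_exponent(e: float, ec: float, params: ScalingParams) -> float:
    """Adaptive exponent P in (0, 1]; saturates at 1 as e, ec -> 0."""
    s = params.e_half + params.ec_half
    p = params.e_half / (abs(e) * s + params.v) + params.ec_half / (abs(ec) * s + params.v)
    return min(p, 1.0)


def input_scaling(x: float, half_width: float, p: float, theta: float) -> float:
    """alpha = (|x|/E)^P + theta with |x| clipped to the half-width E."""
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    if not 0 < p <= 1:
        raise ValueError("exponent P must lie in (0, 1]")
    ratio = min(abs(x), half_width) / half_width
    return ratio**p + theta


def output_scaling(alpha_e: float, alpha_ec: float, theta: float) -> float:
    """beta = (alpha_e + alpha_ec)/2 + theta."""
    return 0.5 * (alpha_e + alpha_ec) + theta


def compute_scale(e: float, ec: float, params: ScalingParams) -> UniverseScale:
    """All scaling factors for the current (e, ec) operating point."""
    p = scaling_exponent(e, ec, params)
    a_e = input_scaling(e, params.e_half, p, params.theta)
    a_ec = input_scaling(ec, params.ec_half, p, params.theta)
    return UniverseScale(
        alpha_e=a_e, alpha_ec=a_ec, beta=output_scaling(a_e, a_ec, params.theta), p=p
    )


def contract_universes(
    params: ScalingParams, scale: UniverseScale
) -> tuple[tuple[float, float], tuple[float, float], tuple[float, float]]:
    """New symmetric (lower, upper) bounds for the e, ec and output universes.

    alpha >= theta by construction, so the half-widths never fall below the
    theta*E floor; the bounds are clamped there defensively all the same.
    """
    th = params.theta

    def bounds(alpha: float, half: float) -> tuple[float, float]:
        hw = max(alpha, th) * half
        return (-hw, hw)

    return (
        bounds(scale.alpha_e, params.e_half),
        bounds(scale.alpha_ec, params.ec_half),
        bounds(scale.beta, params.out_half),
    )
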