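"""Dual-input quad-output Mamdani fuzzy inference and the fuzzy PID law.

The controller reads the temperature error e = Tset - Ti and its per-step
rate ec, fuzzifies both over seven evenly spaced triangular sets
(NB, NM, NS, ZO, PS, PM, PB), fires the 49-rule table with min (AND)
activation and max aggregation, and defuzzifies four channels:

* dKP, dKI, dKD — gain corrections, area-centroid defuzzified on the
  output universe, added to the base PID gains;
* lambda — the positive/negative-pressure ventilation split in [0, 1],
  defuzzified by the height (center-of-sets) method so that a full-strength
  NB maps exactly to 0 and PB to 1.

The discrete PID law is positional,

    u = (KP + dKP)*e + (KI + dKI)*sum(e) + (KD + dKD)*ec,

with the integral accumulated by the rectangle rule in units of control
steps and clamped so the integral term alone can never exceed the actuator
span (anti-windup). Disabling the fuzzy stage reduces the law bit-exactly
to a fixed-gain PID; enabling universe adaptation yields the
variable-universe variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

try:
    from importlib import resources
except ImportError:  # pragma: no cover
    import importlib_resources as resources  # type: ignore

from .variable_universe import ScalingParams, UniverseScale, compute_scale, contract_universes

__all__ = [
    "LABELS",
    "FuzzyUniverse",
    "FuzzyRuleTable",
    "GainSchedule",
    "ControllerState",
    "FuzzyPID",
    "fuzzify",
    "infer",
    "defuzzify",
    "lambda_from_strengths",
    "load_rules",
]

LABELS: tuple[str, ...] = ("NB", "NM", "NS", "ZO", "PS", "PM", "PB")
_LABEL_INDEX = {name: i for i, name in enumerate(LABELS)}
N_LABELS = 7
#: output channels in rule-table cell order
CHANNELS: tuple[str, ...] = ("dkp", "dki", "dkd", "lam")


@dataclass(frozen=True)
class FuzzyUniverse:
    """Symmetric-layout universe with seven triangular sets, 50 % overlap.

    Term centers are evenly spaced from ``lower`` to ``upper``; each triangle
    peaks at its center and reaches zero at the neighbouring centers. Inputs
    outside the bounds are clipped, so the end terms behave as shoulders.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("degenerate universe: lower must be < upper")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, N_LABELS)

    @property
    def half_width(self) -> float:
        """Distance between adjacent term centers."""
        return (self.upper - self.lower) / (N_LABELS - 1)


def fuzzify(x: float, universe: FuzzyUniverse) -> np.ndarray:
    """Membership degrees of ``x`` in the seven sets; at most two nonzero."""
    lo, hi = universe.lower, universe.upper
    x = min(max(x, lo), hi)
    h = universe.half_width
    mu = np.zeros(N_LABELS)
    pos = (x - lo) / h
    k = min(int(pos), N_LABELS - 2)
    t = pos - k
    mu[k] = 1.0 - t
    mu[k + 1] = t
    return mu


@dataclass(frozen=True)
class FuzzyRuleTable:
    """7x7 rule grid indexed (ec-term, e-term); cells are 4-tuples of label
    indices for the dKP, dKI, dKD and lambda channels."""

    grid: tuple[tuple[tuple[int, int, int, int], ...], ...]

    def __post_init__(self) -> None:
        if len(self.grid) != N_LABELS or any(len(row) != N_LABELS for row in self.grid):
            raise ValueError("rule table must be 7x7")

    def cell(self, ec_label: str, e_label: str) -> tuple[str, str, str, str]:
        out = self.grid[_LABEL_INDEX[ec_label]][_LABEL_INDEX[e_label]]
        return tuple(LABELS[k] for k in out)  # type: ignore[return-value]

    @classmethod
    def from_csv(cls, text: str, transpose: bool = False) -> "FuzzyRuleTable":
        """Parse the plain-text dialect: header row of e-terms, one row per
        ec-term, cells like ``PB/NB/PS/PB``. ``transpose`` swaps the roles of
        rows and columns for orientation sensitivity tests."""
        lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
        header = [c.strip() for c in lines[0].split(",")][1:]
        if header != list(LABELS):
            raise ValueError(f"rule table columns must be {LABELS}, got {header}")
        rows: list[list[tuple[int, int, int, int]]] = []
        seen: list[str] = []
        for ln in lines[1:]:
            cells = [c.strip() for c in ln.split(",")]
            seen.append(cells[0])
            row = []
            for cell in cells[1:]:
                parts = cell.split("/")
                if len(parts) != 4 or any(p not in _LABEL_INDEX for p in parts):
                    raise ValueError(f"malformed rule cell {cell!r}")
                row.append(tuple(_LABEL_INDEX[p] for p in parts))
            if len(row) != N_LABELS:
                raise ValueError("each rule row needs 7 cells")
            rows.append(row)  # type: ignore[arg-type]
        if seen != list(LABELS):
            raise ValueError(f"rule table rows must be {LABELS}, got {seen}")
        if transpose:
            rows = [list(r) for r in zip(*rows)]
        return cls(grid=tuple(tuple(r) for r in rows))


def load_rules(path: Optional[str | Path] = None, transpose: bool = False) -> FuzzyRuleTable:
    """Load the shipped 49-rule table, or a user table in the same dialect."""
    if path is None:
        text = resources.files("coopclim").joinpath("data/fuzzy_rules.csv").read_text()
    else:
        text = Path(path).read_text()
    return FuzzyRuleTable.from_csv(text, transpose=transpose)


def infer(mu_e: np.ndarray, mu_ec: np.ndarray, rules: FuzzyRuleTable) -> np.ndarray:
    """Fire the rule base: min activation, max aggregation per output term.

    Returns a (4, 7) array of aggregated strengths, one row per channel.
    """
    out = np.zeros((4, N_LABELS))
    for i in range(N_LABELS):
        wi = mu_ec[i]
        if wi == 0.0:
            continue
        row = rules.grid[i]
        for j in range(N_LABELS):
            w = min(wi, mu_e[j])
            if w == 0.0:
                continue
            cell = row[j]
            for ch in range(4):
                k = cell[ch]
                if w > out[ch, k]:
                    out[ch, k] = w
    return out


def defuzzify(strengths: np.ndarray, universe: FuzzyUniverse, n_grid: int = 201) -> float:
    """Area centroid of the max-aggregated clipped output triangles."""
    total = float(strengths.sum())
    if total == 0.0:
        warnings.warn("all-zero fuzzy output; returning universe midpoint", stacklevel=2)
        return 0.5 * (universe.lower + universe.upper)
    xs = np.linspace(universe.lower, universe.upper, n_grid)
    centers = universe.centers
    h = universe.half_width
    agg = np.zeros(n_grid)
    for k in range(N_LABELS):
        w = strengths[k]
        if w == 0.0:
            continue
        tri = 1.0 - np.abs(xs - centers[k]) / h
        np.maximum(agg, np.minimum(w, np.clip(tri, 0.0, None)), out=agg)
    area = agg.sum()
    return float((xs * agg).sum() / area)


def lambda_from_strengths(strengths: np.ndarray) -> float:
    """Crisp ventilation split from the lambda channel, in [0, 1].

    Height (center-of-sets) defuzzification with the seven term centers
    mapped affinely onto [0, 1]: NB -> 0, ZO -> 0.5, PB -> 1.
    """
    total = float(strengths.sum())
    if total == 0.0:
        return 0.5
    positions = np.linspace(0.0, 1.0, N_LABELS)
    lam = float((strengths * positions).sum() / total)
    return min(max(lam, 0.0), 1.0)


@dataclass(frozen=True)
class GainSchedule:
    """Base PID gains of one season."""

    kp: float
    ki: float
    kd: float
    season: str = ""

    def __post_init__(self) -> None:
        if not (self.kp > 0 and self.ki > 0 and self.kd > 0):
            raise ValueError("gains must be > 0")


@dataclass
class ControllerState:
    """Mutable controller memory: integral accumulator and previous error."""

    integral: float = 0.0  # degC * steps
    prev_error: Optional[float] = None
    last_scale: Optional[UniverseScale] = None
    last_gains: tuple[float, float, float] = (0.0, 0.0, 0.0)
    last_lambda: float = 0.0


@dataclass
class FuzzyPID:
    """Fixed, fuzzy or variable-universe fuzzy PID temperature controller.

    Modes
    -----
    ``fuzzy_enabled=False``            -> plain fixed-gain PID (lambda held at
                                          ``lambda_default``).
    ``fuzzy_enabled=True``             -> FPID with the 49-rule table.
    ``... + adapt_universe=True``      -> VFPID (universes rescaled online).
    ``zero_corrections=True``          -> runs the fuzzy pipeline but forces
                                          the corrections to zero (degeneracy
                                          checks against plain PID).
    ``freeze_scales=True``             -> VFPID with all scaling factors
                                          pinned at 1 (degeneracy checks
                                          against FPID).

    ``dt_ref`` is the reference control period (s): the integral and the
    error rate are expressed per ``dt_ref`` so the printed universes
    ([-3, 3] degC for e, [-1.5, 1.5] degC/step for ec) keep their meaning.
    """

    gains: GainSchedule
    rules: Optional[FuzzyRuleTable] = None
    scaling: ScalingParams = field(default_factory=ScalingParams)
    fuzzy_enabled: bool = True
    adapt_universe: bool = False
    zero_corrections: bool = False
    freeze_scales: bool = False
    lambda_default: float = 0.0
    dt_ref: float = 60.0
    u_span: Optional[float] = None  # anti-windup limit on the integral term
    channel_scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    state: ControllerState = field(default_factory=ControllerState)

    def __post_init__(self) -> None:
        if self.fuzzy_enabled and self.rules is None:
            self.rules = load_rules()

    def reset(self) -> None:
        self.state = ControllerState()

    def _universes(
        self, e: float, ec: float
    ) -> tuple[FuzzyUniverse, FuzzyUniverse, FuzzyUniverse]:
        p = self.scaling
        if self.adapt_universe:
            scale = compute_scale(e, ec, p)
            if self.freeze_scales:
                scale = UniverseScale(alpha_e=1.0, alpha_ec=1.0, beta=1.0, p=scale.p)
            self.state.last_scale = scale
            (elo, ehi), (eclo, echi), (ulo, uhi) = contract_universes(p, scale)
            return (
                FuzzyUniverse(elo, ehi),
                FuzzyUniverse(eclo, echi),
                FuzzyUniverse(ulo, uhi),
            )
        return (
            FuzzyUniverse(-p.e_half, p.e_half),
            FuzzyUniverse(-p.ec_half, p.ec_half),
            FuzzyUniverse(-p.out_half, p.out_half),
        )

    def step(self, setpoint: float, ti: float, dt: float = 60.0) -> tuple[float, float]:
        """One control step; returns (u, lambda) and advances the state."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        steps = dt / self.dt_ref
        e = setpoint - ti
        ec = 0.0 if self.state.prev_error is None else (e - self.state.prev_error) / steps
        self.state.prev_error = e

        dkp = dki = dkd = 0.0
        lam = self.lambda_default
        if self.fuzzy_enabled:
            e_uni, ec_uni, out_uni = self._universes(e, ec)
            mu_e = fuzzify(e, e_uni)
            mu_ec = fuzzify(ec, ec_uni)
            strengths = infer(mu_e, mu_ec, self.rules)  # type: ignore[arg-type]
            if not self.zero_corrections:
                dkp = defuzzify(strengths[0], out_uni) * self.channel_scales[0]
                dki = defuzzify(strengths[1], out_uni) * self.channel_scales[1]
                dkd = defuzzify(strengths[2], out_uni) * self.channel_scales[2]
                # the split keeps its initial universe system: only the e, ec
                # and U domains are rescaled online, so lambda is inferred
                # from the unscaled memberships (otherwise a contracted input
                # universe reduces lambda to the sign of the error and the
                # inlet split flaps between its extremes at every crossing)
                if self.adapt_universe:
                    p = self.scaling
                    mu_e0 = fuzzify(e, FuzzyUniverse(-p.e_half, p.e_half))
                    mu_ec0 = fuzzify(ec, FuzzyUniverse(-p.ec_half, p.ec_half))
                    lam_strengths = infer(mu_e0, mu_ec0, self.rules)[3]  # type: ignore[index]
                else:
                    lam_strengths = strengths[3]
                lam = lambda_from_strengths(lam_strengths)

        kp = self.gains.kp + dkp
        ki = self.gains.ki + dki
        kd = self.gains.kd + dkd
        self.state.integral += e * steps
        if self.u_span is not None and ki > 0:
            cap = self.u_span / ki
            self.state.integral = min(max(self.state.integral, -cap), cap)
        u = kp * e + ki * self.state.integral + kd * ec
        self.state.last_gains = (kp, ki, kd)
        self.state.last_lambda = lam
        return u, lam


def controller_step(
    setpoint: float,
    ti: float,
    controller: FuzzyPID,
    dt: float = 60.0,
) -> tuple[float, float, ControllerState]:
    """Functional wrapper: one step of ``controller``; returns (u, lambda, state)."""
    u, lam = controller.step(setpoint, ti, dt)
    return u, lam, controller.state
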