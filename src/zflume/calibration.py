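"""Flume calibration: meter lines, PWM-vs-velocity polynomials, inverse lookup.

Two procedures are implemented.

1. **Flow-meter calibration** — a bucket test: water pumped for a fixed
   period is collected and weighed while the meter's pulse frequency is
   logged.  An ordinary least-squares line ``flow = m * rate + x`` maps the
   pulse rate (1/s) to volumetric flow (ml/s); at run time the controller
   inverts each 4 s pulse count with ``flow = (p / s) * m + x``.

2. **PWM calibration** (the controller's sweep mode) — the pumps are driven
   through a descending series of PWM levels, holding each for ``stage_s``
   seconds and averaging the *meter-derived* velocity over the final
   ``tail_s`` seconds.  A second-order polynomial ``PWM = c0 + c1*v +
   c2*v**2`` is fitted to the (velocity, PWM) points so that any target
   velocity can be converted to an integer PWM command.

The polynomial is fitted as PWM-on-velocity (not velocity-on-PWM) because
the run-time lookup needs a PWM command for a target velocity; levels at
which the pump stalled (no pulses in the averaging window) are flagged and
excluded from the fit since zero-flow points do not belong to the quadratic
branch.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .hardware import PWM_MAX, PWM_OFF, MeterModel, meter_pulses

__all__ = [
    "FlowMeterCal",
    "PwmCal",
    "SweepPoint",
    "fit_meter",
    "flow_from_pulses",
    "bucket_test",
    "run_pwm_sweep",
    "fit_pwm",
    "pwm_for_velocity",
    "save_cal",
    "load_cal",
]


@dataclass
class FlowMeterCal:
    """Linear meter calibration: ``flow = m * pulse_rate + x``.

    ``m`` is the slope in ml per pulse, ``x`` the intercept in ml/s (the
    small flow at which the turbine first turns).
    """

    meter_id: int
    m: float
    x: float
    r2: float

    def __post_init__(self) -> None:
        # a zero slope is degenerate (flat pairs) but representable; negative
        # slopes would mean the turbine slows with flow and are rejected
        if self.m < 0:
            raise ValueError(f"meter slope must be >= 0, got {self.m}")
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError(f"r2 must be in [0, 1], got {self.r2}")


@dataclass
class PwmCal:
    """Quadratic PWM calibration: ``PWM = c0 + c1*v + c2*v**2``."""

    c0: float
    c1: float
    c2: float
    regime: str
    v_min: float
    v_max: float
    r2: float
    monotone_warning: bool = False
    scenario_hash: str | None = None

    def __post_init__(self) -> None:
        if self.regime not in ("slow", "fast"):
            raise ValueError(f"regime must be 'slow' or 'fast', got {self.regime!r}")

    def predict(self, v: float) -> float:
        """Unrounded polynomial value at velocity ``v`` (cm/s)."""
        return self.c0 + self.c1 * v + self.c2 * v * v


@dataclass
class SweepPoint:
    velocity: float
    pwm: int
    stalled: bool = False


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r^2 of an ordinary least-squares line."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate x-range: need >= 2 distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return float(slope), float(intercept), r2


def fit_meter(pairs, meter_id: int = 1) -> FlowMeterCal:
    """Fit the linear meter calibration from (pulse rate 1/s, flow ml/s) pairs."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 calibration pairs")
    rates = np.array([p[0] for p in pairs], float)
    flows = np.array([p[1] for p in pairs], float)
    if np.ptp(rates) == 0:
        raise ValueError("degenerate pulse-rate range")
    m, x, r2 = _ols_line(rates, flows)
    return FlowMeterCal(meter_id=meter_id, m=m, x=x, r2=min(max(r2, 0.0), 1.0))


def flow_from_pulses(p: int, s: float, cal: FlowMeterCal) -> float:
    """Volumetric flow (ml/s) from ``p`` pulses counted over ``s`` seconds."""
    if p < 0 or int(p) != p:
        raise ValueError(f"pulse count must be a non-negative integer, got {p}")
    if not s > 0:
        raise ValueError("window must be > 0")
    return (p / s) * cal.m + cal.x


def bucket_test(meter: MeterModel, flows, window: float = 60.0) -> list[tuple[float, float]]:
    """Simulate the volumetric bucket test at the given true flows (ml/s).

    Returns (pulse rate, flow) pairs suitable for :func:`fit_meter`.  A fresh
    carry is used per point, as each bucket run starts from rest.
    """
    pairs = []
    for f in flows:
        meter.reset()
        p = meter_pulses(meter, f, window)
        pairs.append((p / window, f))
    meter.reset()
    return pairs


def run_pwm_sweep(controller, levels: int = 10, stage_s: float = 30.0,
                  tail_s: float = 15.0, pwm_min: int = 45,
                  stall_margin: int = 10) -> list[SweepPoint]:
    """Drive the pumps through a descending PWM series and measure velocity.

    ``controller`` is a configured :class:`~zflume.controller.FlumeController`
    with meter calibrations loaded.  Each level is held for ``stage_s``
    seconds; the reported velocity is the mean of the meter-derived (not
    ground-truth) velocities over the final ``tail_s`` seconds.  Levels with
    no pulses in the averaging window are flagged as stalled.
    """
    if levels < 3:
        raise ValueError("need at least 3 sweep levels")
    if not stage_s > tail_s > 0:
        raise ValueError("require stage_s > tail_s > 0")
    pwm_hi = controller.min_stall_pwm() - stall_margin
    if pwm_hi <= pwm_min:
        raise ValueError("sweep range is empty; lower pwm_min or stall_margin")
    pwm_levels = np.round(np.linspace(pwm_hi, pwm_min, levels)).astype(int)
    points: list[SweepPoint] = []
    for pwm in pwm_levels:
        records = controller.hold_pwm(int(pwm), stage_s)
        tail = [r for r in records if r.t - records[0].t >= stage_s - tail_s]
        pulses = sum(r.pulses1 + r.pulses2 for r in tail)
        vbar = float(np.mean([r.velocity for r in tail]))
        points.append(SweepPoint(velocity=vbar, pwm=int(pwm), stalled=pulses == 0))
    return points


def fit_pwm(points, regime: str = "fast", scenario_hash: str | None = None) -> PwmCal:
    """Least-squares quadratic ``PWM = c0 + c1*v + c2*v**2`` through sweep points.

    Stalled points are excluded.  If the fitted mapping is not monotone
    decreasing over the calibrated velocity range, a warning is recorded in
    the calibration metadata (the inverse lookup would be ambiguous there).
    """
    pts = [p for p in points if not getattr(p, "stalled", False)]
    if len(pts) < 4:
        raise ValueError(f"need at least 4 non-stalled points, got {len(pts)}")
    v = np.array([p.velocity for p in pts], float)
    y = np.array([p.pwm for p in pts], float)
    c2, c1, c0 = np.polyfit(v, y, 2)
    resid = y - (c0 + c1 * v + c2 * v * v)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    v_min, v_max = float(v.min()), float(v.max())
    # derivative c1 + 2*c2*v must stay negative over the calibrated range
    dmin = c1 + 2 * c2 * v_min
    dmax = c1 + 2 * c2 * v_max
    mono_warn = not (dmin < 0 and dmax < 0)
    if mono_warn:
        warnings.warn("fitted PWM mapping is not monotone decreasing over the "
                      "calibrated range", stacklevel=2)
    return PwmCal(c0=float(c0), c1=float(c1), c2=float(c2), regime=regime,
                  v_min=v_min, v_max=v_max, r2=min(max(r2, 0.0), 1.0),
                  monotone_warning=mono_warn, scenario_hash=scenario_hash)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pwm_for_velocity(cal: PwmCal, v: float, shutoff: bool = False) -> int:
    """Integer PWM command for target velocity ``v`` (cm/s).

    Rounds half away from zero and clamps to [0, 255].  A shut-off command
    bypasses the calibration entirely and returns 255.  Targets outside the
    calibrated range are evaluated at the nearest range edge with a warning.
    """
    if shutoff:
        return PWM_OFF
    if v < 0:
        raise ValueError("target velocity must be >= 0")
    if v < cal.v_min or v > cal.v_max:
        warnings.warn(
            f"target velocity {v} cm/s outside calibrated range "
            f"[{cal.v_min:.3g}, {cal.v_max:.3g}]; clamping", stacklevel=2)
        v = min(max(v, cal.v_min), cal.v_max)
    pwm = _round_half_away(cal.predict(v))
    return min(max(pwm, 0), PWM_MAX)


def save_cal(cal, path) -> None:
    """Write a calibration record (meter or PWM) as JSON."""
    kind = "meter" if isinstance(cal, FlowMeterCal) else "pwm"
    with open(path, "w") as fh:
        json.dump({"kind": kind, **asdict(cal)}, fh, indent=2)
        fh.write("\n")


def load_cal(path):
    with open(path) as fh:
        d = json.load(fh)
    kind = d.pop("kind", None)
    if kind == "meter":
        return FlowMeterCal(**d)
    if kind == "pwm":
        return PwmCal(**d)
    raise ValueError(f"unknown calibration kind {kind!r} in {path}")
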