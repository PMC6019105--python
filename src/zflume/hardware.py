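"""Ground-truth simulated flume hardware.

The simulated rig mirrors a small zebrafish-scaled swim tunnel: water is
pulled through a cylindrical working section by two magnetically driven
spherical-impeller pumps, each sitting in series with a Hall-effect turbine
flow meter.  The pumps are commanded with an 8-bit PWM value (0-255) that is
*inversely* related to output: 0 is full flow and 255 shuts the pump off.

Ground truth for each pump is the analytic inverse of a second-order
polynomial ``PWM = c0 + c1*v + c2*v**2`` relating the working-section
velocity ``v`` (cm/s) to the commanded PWM.  Two stock characteristics are
provided: a fast (unrestricted, both pumps) curve and a slow curve measured
with pump 2 valved off and pump 1's outlet valve partially closed, which is
the configuration used for larvae and juveniles.

Time advances in discrete 1-second ticks; acquisition windows in the
controller aggregate ticks, so the 4 s count window and 5 s cycle period are
exact multiples of the tick.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FAST_PUMP_POLY",
    "SLOW_PUMP_POLY",
    "PWM_MAX",
    "PWM_OFF",
    "WorkingSection",
    "PumpModel",
    "MeterModel",
    "ProbeModel",
    "FlumeHardware",
    "pump_flow",
    "meter_pulses",
    "section_velocity",
    "fast_scenario",
    "slow_scenario",
    "load_scenario",
    "save_scenario",
]

PWM_MAX = 255
#: Commanding 255 shuts the pumps off regardless of calibration.
PWM_OFF = 255

#: Fast-regime (both pumps, no restriction) velocity->PWM characteristic.
FAST_PUMP_POLY = (244.4, -1.374, -0.021)
#: Slow-regime (pump 2 off, pump 1 outlet valve partially closed) characteristic.
SLOW_PUMP_POLY = (242.8, -8.430, -1.042)


@dataclass
class WorkingSection:
    """Cylindrical swimming chamber.

    ``csa`` is the interior cross-sectional area in cm^2 and ``length`` the
    screen-to-screen distance in cm.  Working-section velocity is total
    volumetric flow divided by ``csa``.
    """

    csa: float = 5.07
    length: float = 12.5

    def __post_init__(self) -> None:
        if not self.csa > 0:
            raise ValueError(f"csa must be > 0, got {self.csa}")
        if not self.length > 0:
            raise ValueError(f"length must be > 0, got {self.length}")


@dataclass
class PumpModel:
    """One spherical-impeller pump and its outlet valve.

    Parameters
    ----------
    inverse_cal
        Coefficients ``(c0, c1, c2)`` of the velocity->PWM polynomial whose
        analytic inverse defines the pump's ground-truth response.  The
        polynomial describes the *working-section* velocity produced by the
        active pump set; ``share`` says what fraction of that velocity this
        pump contributes (0.5 per pump when both run, 1.0 for a lone pump).
    restriction
        Outlet-valve scale factor in (0, 1] multiplying the output flow.
    stall_pwm
        PWM value at and above which the impeller stalls and flow snaps to 0.
    noise_sd
        Relative (multiplicative Gaussian) flow noise per 1 s tick.
    """

    pump_id: int = 1
    inverse_cal: tuple[float, float, float] = FAST_PUMP_POLY
    share: float = 0.5
    restriction: float = 1.0
    stall_pwm: int = 250
    noise_sd: float = 0.005
    enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pump_id not in (1, 2):
            raise ValueError("pump_id must be 1 or 2")
        if not 0 < self.restriction <= 1:
            raise ValueError(f"restriction must be in (0, 1], got {self.restriction}")
        if not 0 < self.share <= 1:
            raise ValueError(f"share must be in (0, 1], got {self.share}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.inverse_cal) != 3:
            raise ValueError("inverse_cal must have three coefficients (c0, c1, c2)")
        self.reset(self.seed)

    def reset(self, seed: int | None = None) -> None:
        """Re-seed the pump's private noise stream."""
        if seed is not None:
            self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)

    def velocity_inverse(self, pwm: float) -> float:
        """Working-section velocity (cm/s) of the active pump set at ``pwm``.

        Solves ``c2*v**2 + c1*v + (c0 - pwm) = 0`` on the physical branch
        (v >= 0, velocity decreasing in PWM) and clamps to 0 for
        ``pwm >= c0``.
        """
        c0, c1, c2 = self.inverse_cal
        if pwm >= c0:
            return 0.0
        if c2 == 0.0:
            v = (pwm - c0) / c1
        else:
            disc = c1 * c1 - 4.0 * c2 * (c0 - pwm)
            if disc < 0:
                return 0.0
            v = (-c1 - math.sqrt(disc)) / (2.0 * c2)
        return max(v, 0.0)

    def flow(self, pwm: int, csa: float, noisy: bool = True) -> float:
        """Volumetric flow (ml/s) through this pump's circuit at ``pwm``."""
        if not 0 <= pwm <= PWM_MAX:
            raise ValueError(f"pwm must be in [0, {PWM_MAX}], got {pwm}")
        if not self.enabled or pwm >= self.stall_pwm:
            return 0.0
        v = self.velocity_inverse(pwm)
        f = self.restriction * self.share * v * csa
        if noisy and self.noise_sd > 0:
            f *= 1.0 + self._rng.normal(0.0, self.noise_sd)
        return max(f, 0.0)


@dataclass
class MeterModel:
    """Hall-effect turbine flow meter.

    Each turbine rotation yields one counted pulse; over a counting window
    the meter reports ``floor(carry + window * (flow - offset_flow) /
    ml_per_pulse)`` pulses, carrying the fractional remainder to the next
    window so the long-run pulse rate is unbiased.
    """

    meter_id: int = 1
    ml_per_pulse: float = 2.44
    offset_flow: float = 0.79
    pulse_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.meter_id not in (1, 2):
            raise ValueError("meter_id must be 1 or 2")
        if not self.ml_per_pulse > 0:
            raise ValueError("ml_per_pulse must be > 0")

    def count(self, flow: float, window: float) -> int:
        """Pulses emitted during ``window`` seconds of constant ``flow`` ml/s."""
        if flow < 0:
            raise ValueError(f"flow must be >= 0, got {flow}")
        if not window > 0:
            raise ValueError("window must be > 0")
        q = self.pulse_residual + window * (flow - self.offset_flow) / self.ml_per_pulse
        if q <= 0:
            # turbine not turning; it cannot owe rotations
            self.pulse_residual = 0.0
            return 0
        pulses = int(math.floor(q))
        self.pulse_residual = q - pulses
        return pulses

    def reset(self) -> None:
        self.pulse_residual = 0.0


@dataclass
class ProbeModel:
    """Reservoir temperature probe (deg C)."""

    setpoint: float = 25.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.reset(self.seed)

    def reset(self, seed: int | None = None) -> None:
        if seed is not None:
            self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)

    def read(self) -> float:
        if self.noise_sd == 0:
            return self.setpoint
        return float(self.setpoint + self._rng.normal(0.0, self.noise_sd))


def pump_flow(pump: PumpModel, pwm: int, ws: WorkingSection | None = None,
              noisy: bool = True) -> float:
    """Volumetric flow (ml/s) produced by ``pump`` at the commanded ``pwm``."""
    ws = ws or WorkingSection()
    return pump.flow(pwm, ws.csa, noisy=noisy)


def meter_pulses(meter: MeterModel, flow: float, window: float) -> int:
    """Integer pulse count for ``flow`` ml/s over ``window`` s (carry kept on the meter)."""
    return meter.count(flow, window)


def section_velocity(f1: float, f2: float, ws: WorkingSection | None = None) -> float:
    """Working-section velocity (cm/s) = (F1 + F2) / CSA."""
    if f1 < 0 or f2 < 0:
        raise ValueError("flows must be >= 0")
    ws = ws or WorkingSection()
    return (f1 + f2) / ws.csa


@dataclass
class FlumeHardware:
    """The complete rig: working section, two pump+meter circuits, probe.

    The circuits are in series, so the flow presented to meter *k* during a
    tick is exactly the flow produced by pump *k* in that tick.
    """

    working_section: WorkingSection = field(default_factory=WorkingSection)
    pump1: PumpModel = field(default_factory=lambda: PumpModel(pump_id=1))
    pump2: PumpModel = field(default_factory=lambda: PumpModel(pump_id=2))
    meter1: MeterModel = field(default_factory=lambda: MeterModel(meter_id=1))
    meter2: MeterModel = field(
        default_factory=lambda: MeterModel(meter_id=2, ml_per_pulse=2.38, offset_flow=1.55)
    )
    probe: ProbeModel = field(default_factory=ProbeModel)

    def reset(self, seed: int | None = None) -> None:
        """Re-seed noise streams and clear meter carries for a fresh run."""
        if seed is None:
            self.pump1.reset(self.pump1.seed)
            self.pump2.reset(self.pump2.seed)
            self.probe.reset(self.probe.seed)
        else:
            seed = int(seed)
            self.pump1.reset(seed)
            self.pump2.reset(seed + 1)
            self.probe.reset(seed + 2)
        self.meter1.reset()
        self.meter2.reset()

    def tick(self, pwm1: int, pwm2: int) -> tuple[float, float]:
        """Advance one second; return the (flow1, flow2) ml/s for this tick."""
        f1 = self.pump1.flow(pwm1, self.working_section.csa)
        f2 = self.pump2.flow(pwm2, self.working_section.csa)
        return f1, f2

    def true_velocity(self, f1: float, f2: float) -> float:
        return section_velocity(f1, f2, self.working_section)

    def to_dict(self) -> dict:
        d = {}
        for name in ("working_section", "pump1", "pump2", "meter1", "meter2", "probe"):
            obj = getattr(self, name)
            rec = {k: v for k, v in dataclasses.asdict(obj).items()}
            if "inverse_cal" in rec:
                rec["inverse_cal"] = list(rec["inverse_cal"])
            d[name] = rec
        return d

    def scenario_hash(self) -> str:
        """Short stable digest of the scenario, recorded in calibration files."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_SECTION_TYPES = {
    "working_section": WorkingSection,
    "pump1": PumpModel,
    "pump2": PumpModel,
    "meter1": MeterModel,
    "meter2": MeterModel,
    "probe": ProbeModel,
}


def load_scenario(source) -> FlumeHardware:
    """Build a :class:`FlumeHardware` from a dict or a JSON scenario file.

    Unknown sections or fields are rejected so typos in scenario files fail
    loudly rather than silently reverting to defaults.
    """
    if isinstance(source, dict):
        data = source
    else:
        with open(source) as fh:
            data = json.load(fh)
    unknown = set(data) - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown scenario sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        rec = dict(data.get(name, {}))
        allowed = {f.name for f in dataclasses.fields(cls)}
        bad = set(rec) - allowed
        if bad:
            raise ValueError(f"unknown fields in scenario section {name!r}: {sorted(bad)}")
        if "inverse_cal" in rec:
            rec["inverse_cal"] = tuple(rec["inverse_cal"])
        kwargs[name] = cls(**rec)
    return FlumeHardware(**kwargs)


def save_scenario(hw: FlumeHardware, path) -> None:
    with open(path, "w") as fh:
        json.dump(hw.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def fast_scenario(noise_sd: float = 0.005, seed: int = 0) -> FlumeHardware:
    """Unrestricted rig: both pumps active, each carrying half the flow."""
    hw = FlumeHardware(
        pump1=PumpModel(pump_id=1, inverse_cal=FAST_PUMP_POLY, share=0.5,
                        noise_sd=noise_sd, seed=seed),
        pump2=PumpModel(pump_id=2, inverse_cal=FAST_PUMP_POLY, share=0.5,
                        noise_sd=noise_sd, seed=seed + 1),
        probe=ProbeModel(seed=seed + 2),
    )
    return hw

def slow_scenario(noise_sd: float = 0.005, seed: int = 0) -> FlumeHardware:
    """Larval/juvenile rig: pump 2 valved off, pump 1 restricted.

    The slow velocity->PWM characteristic is the one measured *at* the
    partially closed valve setting, so it is stored directly as pump 1's
    ground truth with a unit share and unit residual restriction.
    """
    hw = FlumeHardware(
        pump1=PumpModel(pump_id=1, inverse_cal=SLOW_PUMP_POLY, share=1.0,
                        noise_sd=noise_sd, seed=seed),
        pump2=PumpModel(pump_id=2, inverse_cal=SLOW_PUMP_POLY, share=1.0,
                        enabled=False, noise_sd=noise_sd, seed=seed + 1),
        probe=ProbeModel(seed=seed + 2),
    )
    return hw
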