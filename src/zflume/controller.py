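"""Run-time flume controller.

Re-creates the microcontroller firmware's behaviour in a virtual clock:

* three operating modes — protocol (run a stored staged schedule), manual
  (potentiometer-driven PWM) and sweep (drive the PWM calibration series);
* the repeating acquisition cycle: count meter pulses for 4 s, convert to
  flow with the linear meter calibrations, read the temperature probe, and
  emit one record every 5 s (the trailing second is idle processing time
  with no pulse counting);
* kill-switch semantics: once the kill line flips, the PWM command is forced
  to 255 (pumps off) from the next acquisition cycle onward, in every mode;
* regime handling: in the fast regime both pumps run at the same PWM; in the
  slow regime pump 2 is powered down with its valve closed, only meter 1 is
  trusted (no flow passes meter 2), and a slow-regime PWM calibration is
  required.

Fish exhaustion is checked every 1 s tick against the true (noisy)
working-section velocity, not only at record boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .calibration import FlowMeterCal, PwmCal, flow_from_pulses, pwm_for_velocity
from .fish import Fish
from .hardware import PWM_MAX, PWM_OFF, FlumeHardware
from .protocols import Protocol

__all__ = ["AcquisitionRecord", "TrialLog", "FlumeController",
           "ConfigurationError", "RangeError", "manual_pwm"]


class ConfigurationError(RuntimeError):
    """Controller started with missing or mismatched calibration."""


class RangeError(RuntimeError):
    """A protocol target falls outside the calibrated velocity range."""


@dataclass
class AcquisitionRecord:
    """One 5 s data package, stamped with the cycle's start time."""

    t: float
    mode: str
    stage_index: int
    target_v: float
    pwm1: int
    pwm2: int
    pulses1: int
    pulses2: int
    f1: float
    f2: float
    velocity: float
    temp: float
    kill: bool = False


@dataclass
class TrialLog:
    """Complete record of one controller session: metadata plus records.

    ``meta`` carries the protocol parameters, regime, calibration
    identifiers, fish id, seed, CSA, terminal status
    (``completed | exhausted | killed``) and, for exhausted trials, the
    exhaustion time and per-stage bookkeeping the analytics need.
    """

    meta: dict
    records: list[AcquisitionRecord] = field(default_factory=list)

    @property
    def status(self) -> str:
        return self.meta.get("status", "unknown")


def manual_pwm(pot_position: float) -> int:
    """Map a potentiometer fraction (0 = no flow, 1 = full flow) to a PWM value."""
    if not 0 <= pot_position <= 1:
        raise ValueError("pot_position must be in [0, 1]")
    return int(math.floor(PWM_MAX * (1.0 - pot_position) + 0.5))


class FlumeController:
    """Virtual FlowControl run-time bound to a :class:`FlumeHardware`."""

    def __init__(self, hardware: FlumeHardware, regime: str = "fast",
                 meter_cals: tuple[FlowMeterCal, FlowMeterCal] | None = None,
                 pwm_cal: PwmCal | None = None,
                 count_window: int = 4, cycle_period: int = 5,
                 mode_timeout_s: float = 1800.0):
        if regime not in ("slow", "fast"):
            raise ValueError(f"regime must be 'slow' or 'fast', got {regime!r}")
        if not 0 < count_window < cycle_period:
            raise ValueError("require 0 < count_window < cycle_period")
        self.hardware = hardware
        self.regime = regime
        self.meter_cals = meter_cals
        self.pwm_cal = None
        if pwm_cal is not None:
            self.set_pwm_cal(pwm_cal)
        self.count_window = int(count_window)
        self.cycle_period = int(cycle_period)
        self.mode_timeout_s = mode_timeout_s
        self.kill_requested = False
        self._t = 0.0

    # -- configuration -----------------------------------------------------

    def set_pwm_cal(self, cal: PwmCal) -> None:
        if cal.regime != self.regime:
            raise ConfigurationError(
                f"PWM calibration is for the {cal.regime!r} regime but the "
                f"controller is configured for {self.regime!r}; re-run the sweep")
        self.pwm_cal = cal

    def configure_slow_regime(self, restriction: float,
                              inverse_cal: tuple[float, float, float] | None = None) -> None:
        """Switch to the larval/juvenile configuration.

        Powers pump 2 down (valve closed), applies the partial outlet-valve
        ``restriction`` to pump 1, and invalidates any PWM calibration —
        the sweep must be re-run at the new valve setting.  ``inverse_cal``
        optionally replaces pump 1's ground-truth characteristic with one
        measured at the restricted setting (the pump then carries the whole
        flow, share 1).
        """
        if not 0 < restriction < 1:
            raise ValueError("restriction must be in (0, 1): the valve is "
                             "partially, not fully, open or closed")
        self.hardware.pump2.enabled = False
        self.hardware.pump1.restriction = restriction
        if inverse_cal is not None:
            self.hardware.pump1.inverse_cal = tuple(inverse_cal)
            self.hardware.pump1.share = 1.0
        self.regime = "slow"
        self.pwm_cal = None

    def min_stall_pwm(self) -> int:
        pumps = [p for p in (self.hardware.pump1, self.hardware.pump2) if p.enabled]
        if not pumps:
            raise ConfigurationError("no enabled pumps")
        return min(p.stall_pwm for p in pumps)

    def kill(self) -> None:
        """Flip the shut-off switch; takes effect from the next cycle."""
        self.kill_requested = True

    def _require_meter_cals(self) -> None:
        if self.meter_cals is None:
            raise ConfigurationError("meter calibrations are required before running")
        if self.regime == "fast" and (self.meter_cals[0] is None or self.meter_cals[1] is None):
            raise ConfigurationError("fast regime needs both meter calibrations")
        if self.regime == "slow" and self.meter_cals[0] is None:
            raise ConfigurationError("slow regime needs the meter-1 calibration")

    # -- acquisition -------------------------------------------------------

    def _commanded_pwms(self, pwm: int) -> tuple[int, int]:
        if self.regime == "fast":
            return pwm, pwm
        return pwm, PWM_OFF

    def _cycle(self, pwm: int, mode: str, stage_index: int, target_v: float,
               fish: Fish | None = None) -> AcquisitionRecord | None:
        """Run one acquisition cycle (``cycle_period`` ticks of 1 s).

        Returns ``None`` if the fish exhausted mid-cycle: the trial stops on
        the spot and the in-progress data package is never completed.
        """
        kill_active = self.kill_requested
        if kill_active:
            pwm = PWM_OFF
        pwm1, pwm2 = self._commanded_pwms(pwm)
        t0 = self._t
        pulses1 = pulses2 = 0
        for tick in range(self.cycle_period):
            f1, f2 = self.hardware.tick(pwm1, pwm2)
            if tick < self.count_window:
                pulses1 += self.hardware.meter1.count(f1, 1.0)
                pulses2 += self.hardware.meter2.count(f2, 1.0)
            if fish is not None and not fish.exhausted:
                v_true = self.hardware.true_velocity(f1, f2)
                fish.step(v_true, 1.0, t=self._t)
                if fish.exhausted:
                    self._t += 1.0
                    return None
            self._t += 1.0
        cal1, cal2 = self.meter_cals
        f1_hat = flow_from_pulses(pulses1, self.count_window, cal1)
        if self.regime == "slow":
            # pump-2 valve is closed; no flow passes meter 2
            f2_hat = 0.0
        else:
            f2_hat = flow_from_pulses(pulses2, self.count_window, cal2)
        velocity = (f1_hat + f2_hat) / self.hardware.working_section.csa
        return AcquisitionRecord(
            t=t0, mode=mode, stage_index=stage_index, target_v=target_v,
            pwm1=pwm1, pwm2=pwm2, pulses1=pulses1, pulses2=pulses2,
            f1=f1_hat, f2=f2_hat, velocity=velocity,
            temp=self.hardware.probe.read(), kill=kill_active)

    def hold_pwm(self, pwm: int, duration_s: float,
                 mode: str = "sweep") -> list[AcquisitionRecord]:
        """Hold a raw PWM command for ``duration_s`` (sweep/manual helper)."""
        self._require_meter_cals()
        n = int(round(duration_s / self.cycle_period))
        if n < 1 or abs(n * self.cycle_period - duration_s) > 1e-9:
            raise ValueError("duration must be a positive multiple of the cycle period")
        return [self._cycle(pwm, mode, 0, float("nan")) for _ in range(n)]

    def manual_mode(self, pot_position: float) -> int:
        """PWM commanded in manual mode at the given potentiometer position."""
        return manual_pwm(pot_position)

    # -- protocol execution ------------------------------------------------

    def run_protocol(self, protocol: Protocol, fish: Fish | None = None,
                     seed: int | None = None) -> TrialLog:
        """Run a staged protocol to completion, exhaustion, or kill.

        Stage *k* covers elapsed time ``[(k-1)*stage_s, k*stage_s)``; the
        exhaustion check runs every tick.  All stage targets must fall in
        the calibrated velocity range, verified before the first command.
        """
        self._require_meter_cals()
        if self.pwm_cal is None:
            raise ConfigurationError("PWM calibration missing; run and fit a sweep first")
        if protocol.regime != self.regime:
            raise ConfigurationError(
                f"protocol {protocol.name!r} is a {protocol.regime!r}-regime "
                f"protocol but the controller is in the {self.regime!r} regime")
        if protocol.stage_s % self.cycle_period != 0:
            raise ValueError("stage duration must be divisible by the cycle period")
        if seed is not None:
            self.hardware.reset(seed)
        else:
            self.hardware.meter1.reset()
            self.hardware.meter2.reset()
        self._t = 0.0
        self.kill_requested = False

        cal = self.pwm_cal
        if protocol.max_stages is not None:
            n_stages = protocol.max_stages
            if protocol.stage_velocity(n_stages) > cal.v_max + 1e-9:
                raise RangeError(
                    f"stage {n_stages} target {protocol.stage_velocity(n_stages)} cm/s "
                    f"exceeds calibrated v_max {cal.v_max:.3g} cm/s")
        else:
            # run until the next target would leave the calibrated range
            n_stages = int(math.floor((cal.v_max - protocol.u0) / protocol.du)) + 1
            if n_stages < 1:
                raise RangeError(
                    f"initial target {protocol.u0} cm/s exceeds calibrated "
                    f"v_max {cal.v_max:.3g} cm/s")
        if protocol.u0 < cal.v_min - 1e-9:
            raise RangeError(
                f"initial target {protocol.u0} cm/s is below calibrated "
                f"v_min {cal.v_min:.3g} cm/s")

        meta = {
            "protocol": protocol.name, "u0": protocol.u0, "du": protocol.du,
            "stage_s": protocol.stage_s, "regime": self.regime,
            "csa": self.hardware.working_section.csa,
            "cycle_period": self.cycle_period, "count_window": self.count_window,
            "fish_id": fish.id if fish is not None else None,
            "fish_sl_mm": fish.sl if fish is not None else None,
            "seed": seed, "scenario_hash": self.hardware.scenario_hash(),
            "pwm_cal": [cal.c0, cal.c1, cal.c2],
            "meter_cal_ids": [c.meter_id if c else None for c in self.meter_cals],
            "status": "completed", "stages_completed": 0,
            "exhaustion_time_s": None,
        }
        log = TrialLog(meta=meta)
        cycles_per_stage = int(protocol.stage_s) // self.cycle_period
        for k in range(1, n_stages + 1):
            target = protocol.stage_velocity(k)
            pwm = pwm_for_velocity(cal, target)
            stage_done = True
            for _ in range(cycles_per_stage):
                rec = self._cycle(pwm, "protocol", k, target, fish)
                if rec is None:
                    stage_done = False
                    break
                log.records.append(rec)
                if rec.kill:
                    meta["status"] = "killed"
                    return log
            if not stage_done:
                meta["status"] = "exhausted"
                meta["exhaustion_time_s"] = fish.exhaustion_time
                meta["stages_completed"] = k - 1
                meta["failed_stage"] = k
                return log
            meta["stages_completed"] = k
        return log
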