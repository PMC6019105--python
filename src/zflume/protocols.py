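"""Staged incremental-velocity protocol model and stock presets.

A protocol is defined by an initial velocity ``u0`` (cm/s), a per-stage
increment ``du`` (cm/s) and a stage duration (s): stage *k* (1-based) holds
the target ``u0 + (k - 1) * du``.  Flow is stepped up stage by stage until
the fish exhausts, the schedule runs out, or the kill switch fires.

Three presets ship with the package, one per life stage:

========  ====  ====  ========  =======
name       u0    du   stage_s   regime
========  ====  ====  ========  =======
larvae     2.0   0.5     30      slow
juvenile   6.0   1.5     30      fast
adult     10.0   2.5     30      fast
========  ====  ====  ========  =======
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources

__all__ = ["Protocol", "stage_velocity", "load_presets", "PRESET_NAMES",
           "load_protocol", "save_protocol"]

PRESET_NAMES = ("larvae", "juvenile", "adult")


@dataclass(frozen=True)
class Protocol:
    name: str
    u0: float
    du: float
    stage_s: float
    max_stages: int | None = None
    regime: str = "fast"

    def __post_init__(self) -> None:
        if not self.u0 > 0:
            raise ValueError("u0 must be > 0")
        if not self.du > 0:
            raise ValueError("du must be > 0")
        if not self.stage_s > 0:
            raise ValueError("stage_s must be > 0")
        if self.regime not in ("slow", "fast"):
            raise ValueError(f"regime must be 'slow' or 'fast', got {self.regime!r}")
        if self.max_stages is not None and self.max_stages < 1:
            raise ValueError("max_stages must be >= 1")

    def stage_velocity(self, k: int) -> float:
        """Target velocity (cm/s) of 1-based stage ``k``."""
        if k < 1 or (self.max_stages is not None and k > self.max_stages):
            raise ValueError(f"stage index {k} out of range")
        return self.u0 + (k - 1) * self.du

    def stage_start(self, k: int) -> float:
        """Elapsed time (s) at which stage ``k`` begins."""
        return (k - 1) * self.stage_s


def stage_velocity(p: Protocol, k: int) -> float:
    """Target velocity (cm/s) of stage ``k`` of protocol ``p``."""
    return p.stage_velocity(k)


def load_presets() -> dict[str, Protocol]:
    """The stock larvae / juvenile / adult presets, keyed by name."""
    presets = {}
    for name in PRESET_NAMES:
        ref = resources.files("zflume.data.presets").joinpath(f"{name}.json")
        presets[name] = _from_dict(json.loads(ref.read_text()))
    return presets


def _from_dict(d: dict) -> Protocol:
    allowed = {"name", "u0", "du", "stage_s", "max_stages", "regime"}
    bad = set(d) - allowed
    if bad:
        raise ValueError(f"unknown protocol fields: {sorted(bad)}")
    return Protocol(**d)


def load_protocol(path) -> Protocol:
    with open(path) as fh:
        return _from_dict(json.load(fh))


def save_protocol(p: Protocol, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(p), fh, indent=2)
        fh.write("\n")
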