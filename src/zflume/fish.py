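"""Synthetic zebrafish swimmers and cohort generators.

Real trials end when the fish is swept against the downstream screen and
does not resume swimming.  To exercise the controller and analytics without
animals, two simple exhaustion models are provided:

``threshold``
    The fish sustains any water velocity up to its limit ``u_limit`` (cm/s)
    and exhausts the first instant the velocity exceeds it.  Deterministic,
    so protocol durations are exactly reproducible.

``reservoir``
    The fish additionally carries a finite anaerobic reserve: swimming above
    ``u_limit`` drains the reserve at ``(velocity - u_limit)`` per second,
    swimming below it refills at ``recovery_rate`` (capped at capacity), and
    exhaustion occurs when the reserve hits zero.  This mimics fish that
    partially swim their final stage.

Cohorts are built from a design table of (age, sex, n) cells.  Standard
length comes from a linear growth model (default slope 0.258 mm/dpf,
intercept 1.377 mm, valid for 14-42 dpf) or an explicit per-cell mean (used
for adults); per-fish relative performance (SL/s) is the cell mean plus
Gaussian noise, and the absolute limit is ``relative * SL`` with SL
converted from mm to cm.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_GROWTH",
    "Fish",
    "CohortCell",
    "CohortSpec",
    "sl_at_age",
    "make_cohort",
    "step_fish",
    "adult_cohort_spec",
    "developmental_cohort",
    "cohort_table",
]

#: Linear growth of standard length over 14-42 dpf: (slope mm/dpf, intercept mm).
DEFAULT_GROWTH = (0.258, 1.377)

#: Mean relative U_max (SL/s) per adult cell: (sex, age_group) -> SL/s.
ADULT_REL_UMAX = {
    ("m", "young"): 15.9,
    ("f", "young"): 13.0,
    ("m", "old"): 13.6,
    ("f", "old"): 10.4,
}

#: Mean relative U_max of 14 dpf larvae (SL/s).
LARVAL_REL_UMAX_14DPF = 12.1

#: Default absolute-U_max developmental trajectory: continuous piecewise line
#: anchored at 14 dpf, breakpoint 28 dpf, slopes in cm/s per dpf.
DEV_BREAKPOINT_DPF = 28.0
DEV_LEFT_SLOPE = 0.698
DEV_RIGHT_SLOPE = 0.344


@dataclass
class Fish:
    """One synthetic swimmer; ``exhausted`` is absorbing within a trial."""

    id: str
    sl: float                      # standard length, mm
    u_limit: float                 # sustainable absolute velocity, cm/s
    age: float | None = None       # dpf (larvae/juveniles) or months (adults)
    age_group: str | None = None   # design label, e.g. "young" / "old"
    sex: str = "unknown"
    model: str = "threshold"
    reserve_capacity: float = 15.0  # reservoir model: cm (excess cm/s * s)
    recovery_rate: float = 0.5      # reservoir refill, per s below the limit
    reserve: float = field(default=None)  # type: ignore[assignment]
    exhausted: bool = False
    exhaustion_time: float | None = None

    def __post_init__(self) -> None:
        if not self.sl > 0:
            raise ValueError("sl must be > 0")
        if not self.u_limit > 0:
            raise ValueError("u_limit must be > 0")
        if self.model not in ("threshold", "reservoir"):
            raise ValueError(f"unknown exhaustion model {self.model!r}")
        if self.sex not in ("m", "f", "unknown"):
            raise ValueError(f"sex must be 'm', 'f' or 'unknown', got {self.sex!r}")
        if self.reserve is None:
            self.reserve = self.reserve_capacity

    @property
    def sl_cm(self) -> float:
        return self.sl / 10.0

    def step(self, velocity: float, dt: float, t: float | None = None) -> "Fish":
        """Advance the exhaustion state by ``dt`` seconds at ``velocity`` cm/s.

        ``t`` (elapsed s at the *start* of the step) is recorded as the
        exhaustion time if the fish fails during this step.
        """
        if self.exhausted:
            raise ValueError("fish is already exhausted; exhaustion is absorbing")
        if not dt > 0:
            raise ValueError("dt must be > 0")
        if self.model == "threshold":
            if velocity > self.u_limit:
                self.exhausted = True
                self.exhaustion_time = t
        else:
            excess = velocity - self.u_limit
            if excess > 0:
                self.reserve -= excess * dt
                if self.reserve <= 0:
                    self.reserve = 0.0
                    self.exhausted = True
                    self.exhaustion_time = t
            else:
                self.reserve = min(self.reserve_capacity,
                                   self.reserve + self.recovery_rate * dt)
        return self


def step_fish(fish: Fish, velocity: float, dt: float, t: float | None = None) -> Fish:
    """Functional wrapper over :meth:`Fish.step`."""
    return fish.step(velocity, dt, t)


def sl_at_age(age: float, growth: tuple[float, float] = DEFAULT_GROWTH) -> float:
    """Standard length (mm) at ``age`` dpf from the linear growth model."""
    slope, intercept = growth
    if growth == DEFAULT_GROWTH and not 14 <= age <= 42:
        warnings.warn(f"age {age} dpf outside the fitted 14-42 dpf range of the "
                      "default growth model", stacklevel=2)
    return slope * age + intercept


@dataclass
class CohortCell:
    """One design cell: ``n`` fish of a given age and sex.

    ``sl_mean`` overrides the growth model (mandatory for adults whose age is
    in months); ``rel_mean``/``rel_sd`` parameterize relative performance in
    SL/s.
    """

    age: float
    sex: str
    n: int
    rel_mean: float
    rel_sd: float = 0.0
    sl_mean: float | None = None
    sl_sd: float = 0.0
    age_group: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1 per cell")
        if self.rel_sd < 0 or self.sl_sd < 0:
            raise ValueError("sds must be >= 0")


@dataclass
class CohortSpec:
    cells: list[CohortCell]
    growth: tuple[float, float] = DEFAULT_GROWTH
    model: str = "threshold"
    seed: int = 0


def make_cohort(spec: CohortSpec) -> list[Fish]:
    """Draw a cohort of :class:`Fish` from a design spec (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)
    counter = itertools.count(1)
    cohort: list[Fish] = []
    for cell in spec.cells:
        sl_mu = cell.sl_mean if cell.sl_mean is not None else sl_at_age(cell.age, spec.growth)
        for _ in range(cell.n):
            sl = sl_mu + (rng.normal(0.0, cell.sl_sd) if cell.sl_sd > 0 else 0.0)
            rel = cell.rel_mean + (rng.normal(0.0, cell.rel_sd) if cell.rel_sd > 0 else 0.0)
            sl = max(sl, 1e-6)
            rel = max(rel, 1e-6)
            fid = f"{cell.sex}{cell.age:g}-{next(counter):03d}"
            cohort.append(Fish(id=fid, sl=sl, u_limit=rel * sl / 10.0,
                               age=cell.age, age_group=cell.age_group,
                               sex=cell.sex, model=spec.model))
    return cohort


def adult_cohort_spec(ns: tuple[int, int, int, int] = (9, 8, 3, 3),
                      rel_sd: float = 1.0,
                      sl_means: tuple[float, float] = (27.0, 29.0),
                      seed: int = 11) -> CohortSpec:
    """Adult 2x2 (sex x age-group) design.

    Cells are ordered (young m, young f, old m, old f) with the stock
    relative-performance means; ``sl_means`` gives the young and old mean
    standard lengths in mm (old adults run slightly longer).
    """
    sl_young, sl_old = sl_means
    cells = [
        CohortCell(age=8, sex="m", n=ns[0], rel_mean=ADULT_REL_UMAX[("m", "young")],
                   rel_sd=rel_sd, sl_mean=sl_young, age_group="young"),
        CohortCell(age=8, sex="f", n=ns[1], rel_mean=ADULT_REL_UMAX[("f", "young")],
                   rel_sd=rel_sd, sl_mean=sl_young, age_group="young"),
        CohortCell(age=22, sex="m", n=ns[2], rel_mean=ADULT_REL_UMAX[("m", "old")],
                   rel_sd=rel_sd, sl_mean=sl_old, age_group="old"),
        CohortCell(age=22, sex="f", n=ns[3], rel_mean=ADULT_REL_UMAX[("f", "old")],
                   rel_sd=rel_sd, sl_mean=sl_old, age_group="old"),
    ]
    return CohortSpec(cells=cells, seed=seed)


def developmental_cohort(ns=(5, 5, 5, 6, 6), ages=(14, 21, 28, 35, 42),
                         breakpoint: float = DEV_BREAKPOINT_DPF,
                         left_slope: float = DEV_LEFT_SLOPE,
                         right_slope: float = DEV_RIGHT_SLOPE,
                         anchor: tuple[float, float] | None = None,
                         noise_sd: float = 0.5, seed: int = 7):
    """Synthetic larval/juvenile absolute-U_max trajectory.

    The mean follows a continuous piecewise line with the given slopes and
    breakpoint; the default anchor puts the 14 dpf mean at the larval
    relative performance times the 14 dpf standard length.  Returns
    ``(ages, umax)`` arrays (dpf, cm/s) with per-fish Gaussian noise.
    """
    if len(ns) != len(ages):
        raise ValueError("ns and ages must have the same length")
    if anchor is None:
        anchor = (14.0, LARVAL_REL_UMAX_14DPF * sl_at_age(14.0) / 10.0)
    x0, y0 = anchor
    y_break = y0 + left_slope * (breakpoint - x0)

    def mean_at(a):
        a = np.asarray(a, float)
        return np.where(a <= breakpoint,
                        y0 + left_slope * (a - x0),
                        y_break + right_slope * (a - breakpoint))

    rng = np.random.default_rng(seed)
    xs = np.repeat(np.asarray(ages, float), ns)
    ys = mean_at(xs) + (rng.normal(0.0, noise_sd, xs.size) if noise_sd > 0 else 0.0)
    return xs, ys


def cohort_table(cohort: list[Fish]):
    """Cohort as a pandas DataFrame (id, age, age_group, sex, sl_mm, u_limit, rel)."""
    import pandas as pd

    rows = []
    for f in cohort:
        rows.append({"id": f.id, "age": f.age, "age_group": f.age_group,
                     "sex": f.sex, "sl_mm": f.sl,
                     "u_limit_cms": f.u_limit, "rel_sls": f.u_limit / f.sl_cm})
    return pd.DataFrame(rows)
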