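"""Trial and cohort analytics.

Trial level
-----------
* :func:`compute_umax` — the maximal swimming speed U_max from an exhausted
  trial log, under three conventions: the last fully completed stage's
  velocity (default), the velocity of the stage during which the fish
  failed, or the Brett interpolation ``last_completed + (fraction of the
  final stage survived) * du``.  For any exhausted trial these satisfy
  ``last_completed <= brett <= failed_stage``.
* :func:`mean_deviation` — controller fidelity: per completed stage, the
  observed velocity is averaged over records starting at least ``discard_s``
  seconds into the stage (the transient after each velocity step is
  ignored), and the absolute deviations from the stage targets are averaged
  across stages.

Cohort level
------------
* :func:`fit_segmented` — continuous two-segment (piecewise linear)
  least-squares regression with a fixed or grid-searched breakpoint, for
  developmental trajectories whose growth rate changes around the
  larva-to-juvenile transition.
* :func:`fit_factorial` — two-way ANOVA with interaction (sex x age group).
  Sums of squares default to Type II, which is well defined for the
  unbalanced designs typical of adult cohorts; Type I is available for
  parity with R's ``aov`` default.  Marginal effects are reported as
  differences of unweighted cell means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .controller import TrialLog

__all__ = ["UmaxResult", "SegmentedFit", "FactorialResult",
           "compute_umax", "mean_deviation", "fit_segmented", "fit_factorial"]

UMAX_DEFINITIONS = ("last_completed", "failed_stage", "brett")


@dataclass
class UmaxResult:
    fish_id: str | None
    status: str                    # "ok" | "completed, no U_max" | "killed, no U_max"
    definition: str
    u_max_abs: float | None = None   # cm/s
    u_max_rel: float | None = None   # SL/s
    stages_completed: int | None = None
    elapsed_s: float | None = None


@dataclass
class SegmentedFit:
    breakpoint: float
    left_slope: float
    right_slope: float
    left_ci: tuple[float, float]
    right_ci: tuple[float, float]
    rss: float
    intercept: float
    estimated: bool
    unidentifiable: bool = False

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        hinge = np.clip(x - self.breakpoint, 0.0, None)
        return (self.intercept + self.left_slope * x
                + (self.right_slope - self.left_slope) * hinge)


@dataclass
class FactorialResult:
    factors: tuple[str, str]
    effects: dict                   # factor -> first-level minus second-level
    F: dict                         # factor / "interaction" -> F statistic
    p: dict
    cell_means: dict                # (level_a, level_b) -> mean
    ss_type: int
    anova_table: object = None


# ---------------------------------------------------------------------------
# U_max and tracking deviation
# ---------------------------------------------------------------------------

def compute_umax(log: TrialLog, sl_mm: float | None = None,
                 definition: str = "last_completed") -> UmaxResult:
    """U_max of an exhausted trial; explicit no-result status otherwise."""
    if definition not in UMAX_DEFINITIONS:
        raise ValueError(f"definition must be one of {UMAX_DEFINITIONS}")
    meta = log.meta
    fish_id = meta.get("fish_id")
    sl_mm = sl_mm if sl_mm is not None else meta.get("fish_sl_mm")
    if log.status != "exhausted":
        return UmaxResult(fish_id=fish_id, status=f"{log.status}, no U_max",
                          definition=definition)
    u0, du, stage_s = meta["u0"], meta["du"], meta["stage_s"]
    completed = meta["stages_completed"]
    elapsed = meta["exhaustion_time_s"]
    last_v = u0 + (completed - 1) * du if completed >= 1 else 0.0
    if definition == "last_completed":
        u = last_v
    elif definition == "failed_stage":
        u = last_v + du if completed >= 1 else u0
    else:  # brett
        frac = (elapsed - completed * stage_s) / stage_s
        frac = min(max(frac, 0.0), 1.0)
        u = last_v + frac * du
    rel = u / (sl_mm / 10.0) if sl_mm else None
    return UmaxResult(fish_id=fish_id, status="ok", definition=definition,
                      u_max_abs=u, u_max_rel=rel,
                      stages_completed=completed, elapsed_s=elapsed)


def mean_deviation(log: TrialLog, discard_s: float = 5.0) -> float:
    """Mean |observed - target| velocity (cm/s) across completed stages.

    Within each completed stage only records whose cycle starts at least
    ``discard_s`` seconds into the stage contribute; a partial final stage
    (exhaustion mid-stage) is excluded.
    """
    meta = log.meta
    stage_s = meta["stage_s"]
    completed = meta.get("stages_completed", 0)
    if completed < 1:
        raise ValueError("no completed stage in this trial")
    devs = []
    for k in range(1, completed + 1):
        recs = [r for r in log.records if r.stage_index == k]
        start = (k - 1) * stage_s
        kept = [r for r in recs if r.t - start >= discard_s]
        if not kept:
            raise ValueError(f"stage {k} has no records past the discard window")
        obs = float(np.mean([r.velocity for r in kept]))
        devs.append(abs(obs - kept[0].target_v))
    return float(np.mean(devs))


# ---------------------------------------------------------------------------
# Segmented (piecewise linear) regression
# ---------------------------------------------------------------------------

def _hinge_fit(x: np.ndarray, y: np.ndarray, psi: float):
    """OLS of y on [1, x, (x - psi)_+]; returns (beta, rss, X)."""
    hinge = np.clip(x - psi, 0.0, None)
    X = np.column_stack([np.ones_like(x), x, hinge])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return beta, rss, X

def _valid_breakpoint(x: np.ndarray, psi: float, min_side: int = 2) -> bool:
    ux = np.unique(x)
    return (np.sum(ux < psi) >= min_side) and (np.sum(ux > psi) >= min_side)


def fit_segmented(x, y, breakpoint="estimate", grid_resolution: float = 0.25,
                  conf_level: float = 0.95) -> SegmentedFit:
    """Continuous two-segment least-squares fit.

    With ``breakpoint="estimate"`` the breakpoint is grid-searched at
    ``grid_resolution`` over the interior of the x-range (candidates must
    leave at least two distinct x values strictly on each side), minimizing
    the residual sum of squares; ties go to the smallest candidate.  Slope
    confidence intervals come from the linear model at the chosen
    breakpoint (conditional on it).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    ux = np.unique(x)
    estimated = breakpoint == "estimate"
    if estimated:
        if ux.size < 4:
            raise ValueError("need at least 4 distinct x values to estimate a breakpoint")
        lo, hi = ux[0], ux[-1]
        cands = np.arange(lo, hi + grid_resolution / 2, grid_resolution)
        cands = np.round(cands / grid_resolution) * grid_resolution
        cands = [float(c) for c in cands if _valid_breakpoint(x, c)]
        if not cands:
            raise ValueError("no admissible breakpoint candidates for this design")
        best = None
        for psi in cands:
            beta, rss, _ = _hinge_fit(x, y, psi)
            if best is None or rss < best[1] - 1e-12:
                best = (psi, rss)
        psi = float(best[0])
    else:
        psi = float(breakpoint)
        if np.sum(ux <= psi) < 2 or np.sum(ux >= psi) < 2:
            raise ValueError("too few distinct x values on one side of the breakpoint")

    beta, rss, X = _hinge_fit(x, y, psi)
    n, k = X.shape
    dof = n - k
    sigma2 = rss / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.pinv(X.T @ X)
    cov = sigma2 * XtX_inv
    left = float(beta[1])
    right = float(beta[1] + beta[2])
    se_left = float(np.sqrt(max(cov[1, 1], 0.0)))
    se_right = float(np.sqrt(max(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2], 0.0)))
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, dof) if dof > 0 else np.inf

    # if a single straight line explains the data equally well, the
    # breakpoint location is unidentifiable
    slope1, icpt1 = np.polyfit(x, y, 1)
    rss_line = float(np.sum((y - (slope1 * x + icpt1)) ** 2))
    unident = rss_line <= rss * (1 + 1e-9) + 1e-12

    return SegmentedFit(
        breakpoint=psi, left_slope=left, right_slope=right,
        left_ci=(left - tcrit * se_left, left + tcrit * se_left),
        right_ci=(right - tcrit * se_right, right + tcrit * se_right),
        rss=rss, intercept=float(beta[0]), estimated=estimated,
        unidentifiable=bool(unident))


# ---------------------------------------------------------------------------
# Two-way factorial ANOVA
# ---------------------------------------------------------------------------

def fit_factorial(table: pd.DataFrame, response: str = "rel_sls",
                  factors: tuple[str, str] = ("sex", "age_group"),
                  level_order: dict | None = None,
                  ss_type: int = 2) -> FactorialResult:
    """Two-way ANOVA with interaction on a fish table.

    ``level_order`` optionally fixes, per factor, the (first, second) level
    pair defining the sign of the marginal effect (first minus second); by
    default levels are taken in order of first appearance.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = factors
    for col in (fa, fb, response):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    if ss_type not in (1, 2):
        raise ValueError("ss_type must be 1 or 2")
    levels_a = list(dict.fromkeys(table[fa]))
    levels_b = list(dict.fromkeys(table[fb]))
    if level_order:
        if fa in level_order:
            levels_a = list(level_order[fa])
        if fb in level_order:
            levels_b = list(level_order[fb])
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")

    cell_means: dict = {}
    for la in levels_a:
        for lb in levels_b:
            sub = table[(table[fa] == la) & (table[fb] == lb)][response]
            if len(sub) == 0:
                raise ValueError(f"empty design cell: {fa}={la!r}, {fb}={lb!r}")
            cell_means[(la, lb)] = float(sub.mean())

    # marginal effects from unweighted cell means
    def marg_a(la):
        return float(np.mean([cell_means[(la, lb)] for lb in levels_b]))

    def marg_b(lb):
        return float(np.mean([cell_means[(la, lb)] for la in levels_a]))

    effects = {
        fa: marg_a(levels_a[0]) - marg_a(levels_a[1]),
        fb: marg_b(levels_b[0]) - marg_b(levels_b[1]),
    }

    df = table[[fa, fb, response]].copy()
    df.columns = ["A", "B", "y"]
    if np.ptp(df["y"].to_numpy(float)) == 0.0:
        # constant response: every sum of squares is exactly zero
        zeros = {fa: 0.0, fb: 0.0, "interaction": 0.0}
        ones = {fa: 1.0, fb: 1.0, "interaction": 1.0}
        return FactorialResult(factors=factors, effects=effects, F=zeros,
                               p=ones, cell_means=cell_means, ss_type=ss_type)
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    with warnings.catch_warnings():
        # constant response data triggers harmless divide-by-zero F warnings
        warnings.simplefilter("ignore")
        anova = sm.stats.anova_lm(model, typ=ss_type)

    def row(name):
        return anova.loc[name]

    F = {fa: float(row("C(A)")["F"]), fb: float(row("C(B)")["F"]),
         "interaction": float(row("C(A):C(B)")["F"])}
    p = {fa: float(row("C(A)")["PR(>F)"]), fb: float(row("C(B)")["PR(>F)"]),
         "interaction": float(row("C(A):C(B)")["PR(>F)"])}
    for d in (F, p):
        for key, val in d.items():
            if np.isnan(val):
                d[key] = 0.0 if d is F else 1.0
    return FactorialResult(factors=factors, effects=effects, F=F, p=p,
                           cell_means=cell_means, ss_type=ss_type,
                           anova_table=anova)
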