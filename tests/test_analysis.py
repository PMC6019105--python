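"""Analytics: U_max definitions, tracking deviation, segmented fit, ANOVA."""

import numpy as np
import pandas as pd
import pytest

import zflume as z
from zflume.controller import AcquisitionRecord, TrialLog


def synthetic_log(targets, observed, stage_s=30, cycle=5, status="completed",
                  stages_completed=None, exhaustion_time=None, u0=None, du=None):
    """Hand-built trial log with one observed velocity per record."""
    records = []
    t = 0.0
    for k, (tv, ov) in enumerate(zip(targets, observed), start=1):
        for _ in range(stage_s // cycle):
            records.append(AcquisitionRecord(
                t=t, mode="protocol", stage_index=k, target_v=tv, pwm1=100,
                pwm2=100, pulses1=10, pulses2=10, f1=1.0, f2=1.0,
                velocity=ov, temp=25.0))
            t += cycle
    meta = {"protocol": "synthetic", "u0": u0 or targets[0],
            "du": du or (targets[1] - targets[0] if len(targets) > 1 else 1.0),
            "stage_s": stage_s, "status": status,
            "stages_completed": stages_completed if stages_completed is not None
            else len(targets),
            "exhaustion_time_s": exhaustion_time, "fish_id": "s1",
            "fish_sl_mm": 4.989}
    return TrialLog(meta=meta, records=records)


class TestComputeUmax:
    @pytest.fixture
    def exhausted_log(self, slow_controller, presets):
        fish = z.Fish(id="l", sl=4.989, u_limit=6.04)
        return slow_controller.run_protocol(presets["larvae"], fish=fish, seed=0)

    def test_definitions_on_stage10_failure(self, exhausted_log):
        last = z.compute_umax(exhausted_log, definition="last_completed")
        failed = z.compute_umax(exhausted_log, definition="failed_stage")
        brett = z.compute_umax(exhausted_log, definition="brett")
        assert last.u_max_abs == pytest.approx(6.0)
        assert failed.u_max_abs == pytest.approx(6.5)
        assert brett.u_max_abs == pytest.approx(6.0)

    def test_relative_umax(self, exhausted_log):
        res = z.compute_umax(exhausted_log, sl_mm=4.989)
        assert res.u_max_rel == pytest.approx(6.0 / 0.4989, abs=0.01)

    def test_definition_ordering_invariant(self, slow_controller, presets):
        for u_limit, model in [(3.2, "threshold"), (5.1, "reservoir"),
                               (6.04, "threshold")]:
            slow_controller.hardware.reset(0)
            fish = z.Fish(id="x", sl=5.0, u_limit=u_limit, model=model,
                          reserve_capacity=5.0)
            log = slow_controller.run_protocol(presets["larvae"], fish=fish, seed=0)
            vals = [z.compute_umax(log, definition=d).u_max_abs
                    for d in ("last_completed", "brett", "failed_stage")]
            assert vals[0] <= vals[1] <= vals[2]

    def test_completed_trial_has_no_umax(self, presets):
        log = synthetic_log([2.0, 2.5], [2.0, 2.5], status="completed")
        res = z.compute_umax(log)
        assert res.status == "completed, no U_max"
        assert res.u_max_abs is None

    def test_rel_times_sl_equals_abs(self, exhausted_log):
        res = z.compute_umax(exhausted_log)
        assert res.u_max_rel * 0.4989 == pytest.approx(res.u_max_abs, rel=1e-9)


class TestMeanDeviation:
    def test_constant_offset_recovered(self):
        targets = [10.0, 12.5, 15.0]
        log = synthetic_log(targets, [t + 0.1 for t in targets])
        assert z.mean_deviation(log) == pytest.approx(0.1, abs=1e-12)

    def test_partial_final_stage_excluded(self):
        log = synthetic_log([2.0, 2.5, 3.0], [2.0, 2.5, 99.0],
                            status="exhausted", stages_completed=2,
                            exhaustion_time=75.0)
        assert z.mean_deviation(log) == pytest.approx(0.0, abs=1e-12)

    def test_no_complete_stage_errors(self):
        log = synthetic_log([2.0], [2.0], status="exhausted",
                            stages_completed=0, exhaustion_time=3.0)
        with pytest.raises(ValueError, match="no completed stage"):
            z.mean_deviation(log)

    def test_noiseless_trial_within_pwm_quantum(self, fast_controller, presets):
        log = fast_controller.run_protocol(presets["adult"], seed=0)
        cal = fast_controller.pwm_cal
        worst_quantum = 1.0 / abs(cal.c1 + 2 * cal.c2 * 10.0)
        assert z.mean_deviation(log) <= worst_quantum


class TestSegmented:
    def brute_force_oracle(self, x, y, cands):
        """All-breakpoints search with an independent hinge solver."""
        best = None
        for psi in cands:
            X = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0, None)])
            beta = np.linalg.pinv(X) @ y
            rss = float(np.sum((y - X @ beta) ** 2))
            if best is None or rss < best[0] - 1e-12:
                best = (rss, psi, beta)
        return best

    def test_exact_piecewise_recovery(self):
        x, y = z.developmental_cohort(noise_sd=0.0)
        fit = z.fit_segmented(x, y)
        assert fit.breakpoint == pytest.approx(28.0, abs=0.25)
        assert fit.left_slope == pytest.approx(0.698, abs=1e-9)
        assert fit.right_slope == pytest.approx(0.344, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_straight_line_flagged_unidentifiable(self):
        x = np.repeat([10.0, 20.0, 30.0, 40.0, 50.0], 3)
        y = 2.0 * x + 1.0
        fit = z.fit_segmented(x, y)
        assert fit.left_slope == pytest.approx(fit.right_slope, abs=1e-6)
        assert fit.unidentifiable

    def test_fixed_breakpoint_equals_constrained_two_lines(self):
        rng = np.random.default_rng(3)
        x = np.repeat([14, 21, 28, 35, 42], 4).astype(float)
        y = np.where(x <= 28, 1 + 0.7 * x, 1 + 0.7 * 28 + 0.35 * (x - 28))
        y = y + rng.normal(0, 0.3, x.size)
        fit = z.fit_segmented(x, y, breakpoint=28.0)
        _, _, beta = self.brute_force_oracle(x, y, [28.0])
        assert fit.left_slope == pytest.approx(beta[1], rel=1e-9)
        assert fit.right_slope == pytest.approx(beta[1] + beta[2], rel=1e-9)

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = np.repeat(np.sort(rng.choice(np.arange(10, 60), 6, replace=False)),
                          3).astype(float)
            bp = float(np.median(np.unique(x)))
            y = np.where(x <= bp, 0.5 * x, 0.5 * bp - 0.3 * (x - bp)) \
                + rng.normal(0, 0.4, x.size)
            fit = z.fit_segmented(x, y, grid_resolution=0.5)
            ux = np.unique(x)
            cands = [c for c in np.arange(ux[0], ux[-1] + 0.25, 0.5)
                     if np.sum(ux < c) >= 2 and np.sum(ux > c) >= 2]
            rss_o, psi_o, _ = self.brute_force_oracle(x, y, cands)
            assert fit.rss == pytest.approx(rss_o, rel=1e-9, abs=1e-9)
            assert fit.breakpoint == pytest.approx(psi_o, abs=1e-9)

    def test_ci_contains_point_estimate(self):
        x, y = z.developmental_cohort(seed=7)
        fit = z.fit_segmented(x, y)
        assert fit.left_ci[0] <= fit.left_slope <= fit.left_ci[1]
        assert fit.right_ci[0] <= fit.right_slope <= fit.right_ci[1]


def balanced_anova_oracle(df, response="y"):
    """Closed-form two-way ANOVA table for a balanced design."""
    a_levels = sorted(df["A"].unique())
    b_levels = sorted(df["B"].unique())
    n = len(df[(df.A == a_levels[0]) & (df.B == b_levels[0])])
    grand = df[response].mean()
    ss_a = sum(len(b_levels) * n * (df[df.A == a][response].mean() - grand) ** 2
               for a in a_levels)
    ss_b = sum(len(a_levels) * n * (df[df.B == b][response].mean() - grand) ** 2
               for b in b_levels)
    ss_cells = sum(n * (df[(df.A == a) & (df.B == b)][response].mean() - grand) ** 2
                   for a in a_levels for b in b_levels)
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = ((df[response] - grand) ** 2).sum()
    ss_err = ss_tot - ss_cells
    df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = len(df) - len(a_levels) * len(b_levels)
    ms = lambda ss, d: ss / d
    mse = ms(ss_err, df_err)
    return {"A": ms(ss_a, df_a) / mse, "B": ms(ss_b, df_b) / mse,
            "AB": ms(ss_ab, df_ab) / mse}


class TestFactorial:
    def make_table(self, ns=(9, 8, 3, 3), sd=1.0, seed=11):
        spec = z.adult_cohort_spec(ns=ns, rel_sd=sd, seed=seed)
        return z.cohort_table(z.make_cohort(spec))

    def test_exact_cell_mean_effects(self):
        tab = self.make_table(sd=0.0)
        res = z.fit_factorial(tab, level_order={"sex": ("m", "f"),
                                                "age_group": ("young", "old")})
        assert res.effects["sex"] == pytest.approx(3.05, abs=1e-9)
        assert res.effects["age_group"] == pytest.approx(2.45, abs=1e-9)

    def test_identical_cells_zero_F(self):
        tab = self.make_table(sd=0.0)
        tab["rel_sls"] = 10.0
        res = z.fit_factorial(tab)
        assert all(f == pytest.approx(0.0, abs=1e-9) for f in res.F.values())

    def test_empty_cell_error_names_cell(self):
        tab = self.make_table()
        tab = tab[~((tab.sex == "m") & (tab.age_group == "old"))]
        with pytest.raises(ValueError, match="sex=.?m.?.*age_group=.?old"):
            z.fit_factorial(tab)

    def test_balanced_matches_closed_form(self):
        tab = self.make_table(ns=(6, 6, 6, 6), sd=1.2, seed=4)
        res = z.fit_factorial(tab, ss_type=2)
        df = tab.rename(columns={"sex": "A", "age_group": "B", "rel_sls": "y"})
        oracle = balanced_anova_oracle(df)
        assert res.F["sex"] == pytest.approx(oracle["A"], rel=1e-9)
        assert res.F["age_group"] == pytest.approx(oracle["B"], rel=1e-9)
        assert res.F["interaction"] == pytest.approx(oracle["AB"], rel=1e-9)

    def test_balanced_ss_partition(self):
        tab = self.make_table(ns=(5, 5, 5, 5), sd=1.0, seed=2)
        res = z.fit_factorial(tab, ss_type=1)
        an = res.anova_table
        total = ((tab.rel_sls - tab.rel_sls.mean()) ** 2).sum()
        assert an["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    def test_type_switchable(self):
        tab = self.make_table()  # unbalanced
        r1 = z.fit_factorial(tab, ss_type=1)
        r2 = z.fit_factorial(tab, ss_type=2)
        assert r1.ss_type == 1 and r2.ss_type == 2
        # interaction term identical across types; main effects may differ
        assert r1.F["interaction"] == pytest.approx(r2.F["interaction"], rel=1e-9)

    def test_significant_effects_on_stock_cohort(self):
        res = z.fit_factorial(self.make_table(),
                              level_order={"sex": ("m", "f"),
                                           "age_group": ("young", "old")})
        assert res.p["sex"] < 0.001
        assert res.p["age_group"] < 0.01
        assert res.p["interaction"] > 0.05
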