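"""Segmented lactate regression, V̇O₂ mapping, and efficiency slopes."""

import numpy as np
import pandas as pd
import pytest

from trainability.simulate import StepProtocol, generate_step_test
from trainability.cpet import edit_breaths, interpolate_and_bin
from trainability.thresholds import (SegmentedLactateModel, compute_slopes,
                                     fit_linear_slopes, fit_oues,
                                     fit_two_breakpoint, map_thresholds_to_vo2,
                                     summarize_stages)

from conftest import make_participant


def pwl(p, b1, b2, s1, s2, s3, c0=1.0):
    p = np.asarray(p, dtype=float)
    return (c0 + s1 * p + s2 * np.clip(p - b1, 0, None)
            + s3 * np.clip(p - b2, 0, None))


def stage_frame(powers, lactate, vo2=None, hr=None):
    powers = np.asarray(powers, dtype=float)
    return pd.DataFrame({
        "power_w": powers,
        "lactate_mmol_l": lactate,
        "vo2_ml_min": vo2 if vo2 is not None else 10.0 * powers + 500.0,
        "hr_bpm": hr if hr is not None else 0.5 * powers + 95.0,
        "has_lactate": ~pd.isna(lactate),
    })


def brute_force_sse(p, y, grid_step=1.0):
    """Independent exhaustive search over all breakpoint pairs."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = np.floor(p.min() / grid_step) * grid_step + grid_step
    hi = np.ceil(p.max() / grid_step) * grid_step - grid_step
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    best = (np.inf, None, None)
    for b1 in grid:
        if (p < b1).sum() < 1:
            continue
        for b2 in grid:
            if b2 <= b1 or (p > b2).sum() < 1:
                continue
            A = np.column_stack([np.ones_like(p), p,
                                 np.clip(p - b1, 0, None),
                                 np.clip(p - b2, 0, None)])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            sse = float(((A @ coef - y) ** 2).sum())
            if sse < best[0] - 1e-12:
                best = (sse, b1, b2)
    return best


class TestSegmentedFit:
    def test_noiseless_exact_recovery(self):
        powers = np.arange(25, 226, 25)
        fit = fit_two_breakpoint(stage_frame(powers, pwl(powers, 100, 175, .005, .05, .2)))
        assert fit.ltp1_po == 100.0
        assert fit.ltp2_po == 175.0
        assert fit.sse < 1e-12

    def test_noiseless_exact_recovery_many_configs(self):
        r = np.random.default_rng(0)
        for _ in range(50):
            powers = np.arange(25, 276, 25)
            b1 = int(r.integers(60, 121))
            b2 = int(r.integers(b1 + 55, 221))
            s1 = r.uniform(0.0, 0.01)
            s2 = s1 + r.uniform(0.01, 0.05)
            s3 = s2 + r.uniform(0.05, 0.2)
            fit = fit_two_breakpoint(stage_frame(powers, pwl(powers, b1, b2, s1, s2, s3)))
            assert (fit.ltp1_po, fit.ltp2_po) == (b1, b2)
            assert fit.sse < 1e-10

    def test_matches_bruteforce_oracle_on_noisy_data(self):
        r = np.random.default_rng(3)
        powers = np.arange(25, 226, 25)
        y = pwl(powers, 90, 160, .004, .04, .18) + r.normal(0, 0.2, powers.size)
        model = SegmentedLactateModel(grid_step=5.0).fit(powers, y)
        sse, b1, b2 = brute_force_sse(powers, y, grid_step=5.0)
        assert model.sse_ == pytest.approx(sse, rel=1e-9)
        assert (model.ltp1_po_, model.ltp2_po_) == (b1, b2)

    def test_piecewise_sse_not_worse_than_single_line(self):
        r = np.random.default_rng(5)
        for seed in range(10):
            rr = np.random.default_rng(seed)
            powers = np.arange(25, 251, 25)
            y = pwl(powers, 100, 180, .004, .05, .15) + rr.normal(0, 0.3, powers.size)
            fit = fit_two_breakpoint(stage_frame(powers, y))
            line = np.polyfit(powers, y, 1)
            sse_line = float(((np.polyval(line, powers) - y) ** 2).sum())
            assert fit.sse <= sse_line + 1e-9

    def test_continuity_at_breakpoints(self):
        powers = np.arange(25, 226, 25)
        y = pwl(powers, 100, 175, .005, .05, .2) + \
            np.random.default_rng(1).normal(0, 0.15, powers.size)
        fit = fit_two_breakpoint(stage_frame(powers, y))
        eps = 1e-6
        for b in (fit.ltp1_po, fit.ltp2_po):
            assert fit.predict(b - eps) == pytest.approx(fit.predict(b + eps), abs=1e-4)

    def test_degenerate_lactate_errors(self):
        powers = np.arange(25, 176, 25)
        with pytest.raises(ValueError, match="no identifiable breakpoints"):
            fit_two_breakpoint(stage_frame(powers, np.full(powers.size, 1.5)))

    def test_too_few_stages_errors(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_two_breakpoint(stage_frame([50, 75, 100], [1.0, 1.5, 3.0]))

    def test_missing_lactate_rows_excluded(self):
        powers = np.arange(25, 226, 25)
        y = pwl(powers, 100, 175, .005, .05, .2)
        y_with_nan = y.copy()
        y_with_nan[3] = np.nan
        fit = fit_two_breakpoint(stage_frame(powers, y_with_nan))
        assert (fit.ltp1_po, fit.ltp2_po) == (100.0, 175.0)

    def test_simulation_recovery_median_within_one_stage(self):
        # noisy lactate (sd 0.2): median LTP1 error within one 25-W increment
        errors = []
        rng = np.random.default_rng(77)
        p = make_participant()
        proto = StepProtocol(lactate_noise_sd=0.2, vo2_noise_sd=0.0, hr_noise_sd=0.0)
        for _ in range(120):
            test = generate_step_test(p, proto, rng=rng)
            stages = summarize_stages(test.breath, test.lactate)
            fit = fit_two_breakpoint(stages)
            errors.append(abs(fit.ltp1_po - p.ltp1_po))
        assert np.median(errors) <= 25.0


class TestStageSummaries:
    def test_noiseless_stage_means_match_truth(self, participant, noiseless_protocol):
        test = generate_step_test(participant, noiseless_protocol)
        stages = summarize_stages(test.breath, test.lactate)
        for _, row in stages.iterrows():
            assert row["hr_bpm"] == pytest.approx(
                min(participant.hr_po_intercept
                    + participant.hr_po_slope * row["power_w"], participant.hr_max),
                abs=1e-9)
            assert row["lactate_mmol_l"] == pytest.approx(
                participant.true_lactate(row["power_w"]), abs=1e-9)

    def test_jittered_means_match_bruteforce_window_average(self, participant):
        test = generate_step_test(participant, StepProtocol(seed=4))
        stages = summarize_stages(test.breath, test.lactate)
        b = test.breath
        t = b["time_s"].to_numpy()
        for _, row in stages.iterrows():
            in_stage = b["power_w"].to_numpy() == row["power_w"]
            t_end = t[in_stage].max()
            w = in_stage & (t >= t_end - 60.0)
            assert row["vo2_ml_min"] == pytest.approx(
                b["vo2_ml_min"].to_numpy()[w].mean(), rel=1e-12)

    def test_missing_lactate_stage_flagged(self, participant, noiseless_protocol):
        test = generate_step_test(participant, noiseless_protocol)
        lac = test.lactate[test.lactate["stage_power_w"] != 75.0]
        stages = summarize_stages(test.breath, lac)
        row = stages[stages["power_w"] == 75.0].iloc[0]
        assert not row["has_lactate"]


class TestVo2Mapping:
    def test_exact_line(self):
        powers = np.arange(25, 226, 25)
        stages = stage_frame(powers, pwl(powers, 100, 175, .005, .05, .2),
                             vo2=10.0 * powers + 500.0)
        fit = map_thresholds_to_vo2(fit_two_breakpoint(stages), stages)
        assert fit.vo2_at_ltp1 == pytest.approx(1500.0)
        assert fit.vo2_at_ltp2 == pytest.approx(2250.0)
        assert fit.vo2_at_ltp2 > fit.vo2_at_ltp1

    def test_matches_closed_form_ols(self, rng):
        powers = np.arange(25, 226, 25).astype(float)
        vo2 = 9.7 * powers + 480 + rng.normal(0, 40, powers.size)
        stages = stage_frame(powers, pwl(powers, 100, 175, .005, .05, .2), vo2=vo2)
        fit = map_thresholds_to_vo2(fit_two_breakpoint(stages), stages)
        X = np.column_stack([np.ones_like(powers), powers])
        beta = np.linalg.solve(X.T @ X, X.T @ vo2)
        assert fit.vo2_at_ltp1 == pytest.approx(beta[0] + beta[1] * fit.ltp1_po, rel=1e-9)


class TestEfficiencySlopes:
    def test_oues_exact(self):
        ve = np.linspace(10, 90, 20)
        df = pd.DataFrame({"ve_l_min": ve, "vo2_ml_min": 1000.0 * np.log10(ve)})
        a, b, r2 = fit_oues(df)
        assert a == pytest.approx(1000.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_ve_rescaling_changes_intercept_only(self, rng):
        ve = np.linspace(12, 80, 25)
        vo2 = 1800 * np.log10(ve) - 500 + rng.normal(0, 30, 25)
        a1, b1, _ = fit_oues(pd.DataFrame({"ve_l_min": ve, "vo2_ml_min": vo2}))
        a2, b2, _ = fit_oues(pd.DataFrame({"ve_l_min": 3.0 * ve, "vo2_ml_min": vo2}))
        assert a2 == pytest.approx(a1, rel=1e-9)
        assert b2 == pytest.approx(b1 - a1 * np.log10(3.0), rel=1e-9)

    def test_nonpositive_ve_errors(self):
        df = pd.DataFrame({"ve_l_min": [10.0, 0.0, 30.0], "vo2_ml_min": [1, 2, 3.0]})
        with pytest.raises(ValueError, match="non-positive"):
            fit_oues(df)

    def test_linear_slopes_exact(self):
        po = np.linspace(25, 200, 15)
        vo2 = 9.5 * po + 300
        hr = 0.03 * vo2 + 60
        df = pd.DataFrame({"power_w": po, "vo2_ml_min": vo2, "hr_bpm": hr})
        s_po, _, s_hr, _ = fit_linear_slopes(df)
        assert s_po == pytest.approx(9.5, abs=1e-9)
        assert s_hr == pytest.approx(0.03, abs=1e-12)

    def test_slopes_match_closed_form_ols(self, rng):
        po = np.linspace(25, 200, 30)
        vo2 = 10.0 * po + 450 + rng.normal(0, 50, 30)
        hr = 0.028 * vo2 + 65 + rng.normal(0, 2, 30)
        df = pd.DataFrame({"power_w": po, "vo2_ml_min": vo2, "hr_bpm": hr})
        s_po, _, s_hr, _ = fit_linear_slopes(df)
        def ols_slope(x, y):
            return float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
        assert s_po == pytest.approx(ols_slope(po, vo2), rel=1e-9)
        assert s_hr == pytest.approx(ols_slope(vo2, hr), rel=1e-9)

    def test_constant_regressor_errors(self):
        df = pd.DataFrame({"power_w": np.full(10, 100.0),
                           "vo2_ml_min": np.arange(10.0),
                           "hr_bpm": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            fit_linear_slopes(df)

    def test_compute_slopes_on_simulated_test(self, participant):
        test = generate_step_test(participant, StepProtocol(seed=2))
        edited, _ = edit_breaths(test.breath)
        slopes = compute_slopes(interpolate_and_bin(edited))
        assert slopes.dvo2_dpo == pytest.approx(participant.vo2_po_slope, rel=0.1)
        assert slopes.oues_a == pytest.approx(participant.oues_a, rel=0.15)
        assert 0 <= slopes.oues_r2 <= 1
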