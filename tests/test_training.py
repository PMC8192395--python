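"""Prescription arithmetic, weekly monitoring decisions, and load metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trainability.simulate import TrainingLogConfig, generate_training_log
from trainability.training import (Prescription, adjust_intensity, clean_hr,
                                   compute_itrimp, compute_session_metrics,
                                   ensemble_week, fit_lactate_weighting,
                                   prescribe_hiit, prescribe_mict)

from conftest import make_participant


def flat_log(power=67.0, hr=140.0, duration=3600):
    t = np.arange(duration, dtype=float)
    return pd.DataFrame({"time_s": t, "power_w": float(power), "hr_bpm": float(hr),
                         "cadence_rpm": 80.0})


class TestPrescribeHiit:
    def test_linear_inversion_example(self):
        po = np.array([50.0, 100.0, 150.0])
        rx = prescribe_hiit(po, 0.5 * po + 95.0, hr_max=190.0)
        powers = dict((lab, pw) for lab, _, pw in rx.phases)
        assert powers["interval"] == 152.0       # (171 - 95) / 0.5
        assert powers["warmup"] == 76.0          # (133 - 95) / 0.5
        assert powers["recovery"] == 30.0
        assert rx.target_hr == pytest.approx(171.0)

    def test_total_duration_43_min(self):
        po = np.array([50.0, 100.0, 150.0])
        rx = prescribe_hiit(po, 0.5 * po + 95.0, hr_max=190.0)
        assert rx.total_duration_s == 2580.0
        assert sum(1 for lab, *_ in rx.phases if lab == "interval") == 4
        assert sum(1 for lab, *_ in rx.phases if lab == "recovery") == 3

    def test_noninvertible_hr_po_errors(self):
        po = np.array([50.0, 100.0, 150.0])
        with pytest.raises(ValueError, match="not invertible"):
            prescribe_hiit(po, 180.0 - 0.2 * po, hr_max=190.0)

    def test_symmetric_hr_noise_unbiased(self):
        # doubling symmetric stage-HR noise leaves the mean prescribed power
        # unchanged within MC error (500 replicates)
        po = np.arange(25.0, 151.0, 25.0)
        true_hr = 0.6 * po + 90.0
        rng = np.random.default_rng(11)
        powers = {1.0: [], 2.0: []}
        for scale in powers:
            for _ in range(500):
                noisy = true_hr + rng.normal(0, scale * 2.0, po.size)
                powers[scale].append(
                    dict((lab, pw) for lab, _, pw in
                         prescribe_hiit(po, noisy, 190.0).phases)["interval"])
        m1, m2 = np.mean(powers[1.0]), np.mean(powers[2.0])
        se = np.sqrt(np.var(powers[2.0], ddof=1) / 500 + np.var(powers[1.0], ddof=1) / 500)
        assert abs(m1 - m2) < 3 * se + 0.5       # 0.5 W for the rounding grid


class TestPrescribeMict:
    def test_90pct_of_ltp1(self):
        rx = prescribe_mict(100.0, 0.5, 95.0)
        assert rx.phases == [("steady", 3600.0, 90.0)]
        assert rx.target_hr == pytest.approx(95.0 + 0.5 * 90.0)

    def test_rounding_rule(self):
        rx = prescribe_mict(83.0, 0.5, 95.0)     # 0.9 * 83 = 74.7 -> 75
        assert rx.phases[0][2] == 75.0

    def test_duration_always_3600(self):
        for ltp1 in (60.0, 83.0, 140.0):
            assert prescribe_mict(ltp1, 0.5, 95.0).total_duration_s == 3600.0

    def test_missing_threshold_errors(self):
        with pytest.raises(ValueError, match="ltp1_po"):
            prescribe_mict(0.0, 0.5, 95.0)


class TestEnsembleWeek:
    def test_three_identical_noiseless_logs(self):
        log = flat_log(hr=150.0, duration=600)
        ens = ensemble_week([log, log.copy(), log.copy()])
        assert np.allclose(ens["hr_bpm"], 150.0)
        assert len(ens) == 120                    # 600 s in 5-s bins

    def test_five_second_bins_match_bruteforce(self):
        rng = np.random.default_rng(4)
        logs = []
        base = 130 + np.cumsum(rng.normal(0, 0.3, 600))
        for _ in range(3):
            log = flat_log(duration=600)
            log["hr_bpm"] = base + rng.normal(0, 1.0, 600)
            logs.append(log)
        ens = ensemble_week(logs)
        cleaned = [clean_hr(l["hr_bpm"])[0] for l in logs]
        mean_hr = np.mean(cleaned, axis=0)
        for k in range(len(ens)):
            assert ens["hr_bpm"].iloc[k] == pytest.approx(
                mean_hr[5 * k: 5 * (k + 1)].mean(), rel=1e-12)

    def test_fewer_sessions_warns(self):
        with pytest.warns(UserWarning, match="3 expected"):
            ensemble_week([flat_log(duration=300)])

    def test_anomaly_removal_rate(self):
        p = make_participant()
        rx = prescribe_mict(100.0, p.hr_po_slope, p.hr_po_intercept)
        caught = total = 0
        for seed in range(5):
            cfg = TrainingLogConfig(anomaly_rate=0.01, hr_noise_sd=2.0, seed=seed)
            data = generate_training_log(rx, p, cfg)
            _, removed = clean_hr(data.log["hr_bpm"])
            caught += removed[data.anomaly_idx].sum()
            total += data.anomaly_idx.size
        assert caught >= 0.9 * total


class TestAdjustIntensity:
    def _mict_rx(self, target=140.0):
        return Prescription(group="MICT", phases=[("steady", 3600.0, 90.0)],
                            target_hr=target)

    def _trace(self, hr):
        t = np.arange(0, 3600, 5.0) + 2.5
        return pd.DataFrame({"time_s": t, "hr_bpm": float(hr)})

    @pytest.mark.parametrize("offset,action", [
        (-5.0, "increase_5w"),
        (-3.5, "increase_5w"),
        (0.0, "hold"),
        (-3.0, "hold"),
        (3.0, "hold"),
        (4.0, "flag_recalibration"),
    ])
    def test_band_decisions(self, offset, action):
        rx = self._mict_rx(140.0)
        decision = adjust_intensity(self._trace(140.0 + offset), rx)
        assert decision.action == action

    def test_increase_applies_to_power(self):
        rx = self._mict_rx(140.0)
        decision = adjust_intensity(self._trace(130.0), rx)
        assert decision.next_prescription.phases[0][2] == 95.0
        assert decision.next_prescription.week == 2

    def test_hiit_interval_windows(self):
        po = np.array([50.0, 100.0, 150.0])
        rx = prescribe_hiit(po, 0.5 * po + 95.0, hr_max=190.0)
        t = np.arange(0, 2580, 5.0) + 2.5
        hr = np.full(t.size, 100.0)
        for start, end, _ in rx.phase_windows("interval"):
            hr[(t >= end - 120) & (t < end)] = 160.0   # observed 160 vs target 171
        decision = adjust_intensity(pd.DataFrame({"time_s": t, "hr_bpm": hr}), rx)
        assert decision.observed_hr == pytest.approx(160.0)
        assert decision.action == "increase_5w"
        powers = dict((lab, pw) for lab, _, pw in decision.next_prescription.phases)
        assert powers["interval"] == 157.0
        assert powers["warmup"] == 76.0              # only intervals adjusted

    def test_power_never_decreases_over_six_weeks(self):
        rng = np.random.default_rng(9)
        rx = self._mict_rx(140.0)
        prev = rx.phases[0][2]
        for week in range(6):
            observed = 140.0 + rng.uniform(-8, 8)
            decision = adjust_intensity(self._trace(observed), rx)
            rx = decision.next_prescription
            assert rx.phases[0][2] >= prev
            prev = rx.phases[0][2]


class TestSessionMetrics:
    def test_printed_mict_example(self):
        # 60 min at 67 W, 71.0 kg body mass
        m = compute_session_metrics(flat_log(67.0, 140.0), po_peak=160.0,
                                    hr_max=190.0, hr_rest=60.0, mass=71.0)
        assert m.total_work_kj == pytest.approx(241.2)
        assert m.relative_work_kj_kg == pytest.approx(3.40, abs=0.005)
        assert m.total_kcal == pytest.approx(241.2 / 4.184)
        assert m.total_kcal == pytest.approx(57.65, abs=0.01)
        assert m.pct_hr_reserve == pytest.approx(100 * (140 - 60) / 130)

    def test_zero_power(self):
        m = compute_session_metrics(flat_log(0.0, 80.0), 160.0, 190.0, 60.0, 70.0)
        assert m.total_work_kj == 0.0
        assert m.total_kcal == 0.0

    def test_hr_bounds_error(self):
        with pytest.raises(ValueError, match="hr_max"):
            compute_session_metrics(flat_log(), 160.0, 60.0, 60.0, 70.0)

    @given(power=st.floats(10, 300), duration=st.integers(60, 4000))
    @settings(max_examples=25, deadline=None)
    def test_kcal_work_identity(self, power, duration):
        m = compute_session_metrics(flat_log(power, 140.0, duration),
                                    200.0, 190.0, 60.0, 70.0)
        assert m.total_kcal * 4.184 == pytest.approx(m.total_work_kj, rel=1e-12)

    def test_interval_adjusted_metrics(self):
        po = np.array([50.0, 100.0, 150.0])
        rx = prescribe_hiit(po, 0.5 * po + 95.0, hr_max=190.0)
        t = np.arange(2580, dtype=float)
        power = np.zeros(2580)
        bounds = np.cumsum([0] + [d for _, d, _ in rx.phases])
        for (lab, dur, pw), s, e in zip(rx.phases, bounds[:-1], bounds[1:]):
            power[int(s):int(e)] = pw
        log = pd.DataFrame({"time_s": t, "power_w": power, "hr_bpm": 150.0,
                            "cadence_rpm": 80.0})
        m = compute_session_metrics(log, 200.0, 190.0, 60.0, 70.0, prescription=rx)
        assert m.interval_mean_power_w == pytest.approx(152.0)
        assert m.interval_pct_po_peak == pytest.approx(76.0)


class TestItrimp:
    def test_resting_hr_zero(self):
        m = compute_itrimp(flat_log(50.0, 60.0, 600), (1.0, 1.92), 190.0, 60.0)
        assert m == 0.0

    def test_closed_form_constant_fraction(self):
        # x = 0.5 for 10 min, weighting (1, 1.92): 10 * 0.5 * e^0.96
        hr = 60.0 + 0.5 * (190.0 - 60.0)
        m = compute_itrimp(flat_log(50.0, hr, 600), (1.0, 1.92), 190.0, 60.0)
        assert m == pytest.approx(10 * 0.5 * np.exp(0.96), rel=1e-9)

    def test_monotone_in_duration(self):
        vals = [compute_itrimp(flat_log(50.0, 150.0, d), (0.8, 1.92), 190.0, 60.0)
                for d in (600, 1200, 2400)]
        assert vals[0] < vals[1] < vals[2]

    def test_individual_weighting_fit_roundtrip(self):
        hr = np.array([110.0, 125.0, 140.0, 155.0, 170.0, 185.0])
        x = (hr - 60.0) / 130.0
        la = 0.8 * np.exp(2.1 * x)
        a, b, fallback = fit_lactate_weighting(la, hr, 190.0, 60.0)
        assert not fallback
        assert a == pytest.approx(0.8, rel=1e-6)
        assert b == pytest.approx(2.1, rel=1e-6)

    def test_weighting_fallback(self):
        with pytest.warns(UserWarning, match="generic"):
            a, b, fallback = fit_lactate_weighting([1.0, np.nan], [110.0, 120.0],
                                                   190.0, 60.0)
        assert fallback and (a, b) == (0.64, 1.92)

    def test_invalid_weighting_errors(self):
        with pytest.raises(ValueError, match="amplitude"):
            compute_itrimp(flat_log(), (-1.0, 1.92), 190.0, 60.0)
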