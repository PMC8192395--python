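"""Training prescription, weekly heart-rate monitoring, and load metrics.

Two work-matched programmes on a cycle ergometer:

* HIIT — 10 min warm-up at the power of 70 % HRmax, then 4 × 4-min
  intervals at the power of 90 % HRmax interspersed with 4-min active
  recoveries at 30 W, and a 5-min cool-down at 30 W (43 min total).
  Interval/warm-up powers are read off the linear HR–power relation fitted
  to the last-30-s stage heart rates of the incremental test.
* MICT — 60 min of continuous cycling at 90 % of the LTP1 power.

Weekly monitoring ensembles the (anomaly-cleaned) heart-rate traces of the
week's sessions into 5-s bins and compares the observed heart rate with a
±3 bpm band around the prescribed one: below the band, next week's workload
increases by 5 W; above it, the ergometer is flagged for recalibration.

Session load metrics: total/relative work and kcal, %PO_peak, %HRmax,
%HR-reserve, and the individualised training impulse (iTRIMP) with an
individually fitted exponential lactate weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

HIIT_WARMUP_S = 600.0
HIIT_INTERVAL_S = 240.0
HIIT_RECOVERY_S = 240.0
HIIT_COOLDOWN_S = 300.0
RECOVERY_POWER_W = 30.0
MICT_DURATION_S = 3600.0
SWD_BPM = 3.0                  # smallest worthwhile difference around target HR
ADJUST_STEP_W = 5.0
#: Generic exponential lactate-weighting constants (fallback when the
#: individual lactate–HR relation cannot be fitted).
GENERIC_WEIGHTING = (0.64, 1.92)


@dataclass
class Prescription:
    """An ordered phase plan for one session.

    ``phases`` is a list of ``(label, duration_s, power_w)``; ``target_hr``
    is the heart rate the plan is meant to elicit (90 % HRmax during HIIT
    intervals; the HR at 90 % LTP1 power for MICT).
    """

    group: str
    phases: list = field(default_factory=list)
    target_hr: float = 0.0
    week: int = 1

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d, _ in self.phases))

    def phase_windows(self, label: str):
        """(start_s, end_s, power_w) of every phase with the given label."""
        out, t = [], 0.0
        for lab, dur, pw in self.phases:
            if lab == label:
                out.append((t, t + dur, pw))
            t += dur
        return out


def fit_hr_po_line(stage_power, stage_hr):
    """OLS heart-rate vs power line from stage summaries → (slope, intercept)."""
    x = np.asarray(stage_power, dtype=float)
    y = np.asarray(stage_hr, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 stages to fit the HR-PO relation")
    res = sps.linregress(x, y)
    if res.slope <= 0:
        raise ValueError("HR-PO relation not invertible (non-positive slope)")
    return float(res.slope), float(res.intercept)


def power_at_hr(hr: float, slope: float, intercept: float) -> float:
    """Invert the HR–power line; rounded to the nearest watt (ergometer resolution)."""
    return float(round((hr - intercept) / slope))


def prescribe_hiit(stage_power, stage_hr, hr_max: float, week: int = 1) -> Prescription:
    """Build the HIIT phase plan from incremental-test stage HR data.

    Warm-up power targets 70 % HRmax, interval power 90 % HRmax, both read
    off the stage HR–power line; recoveries and cool-down at 30 W.
    """
    slope, intercept = fit_hr_po_line(stage_power, stage_hr)
    warmup_w = power_at_hr(0.70 * hr_max, slope, intercept)
    interval_w = power_at_hr(0.90 * hr_max, slope, intercept)
    phases = [("warmup", HIIT_WARMUP_S, warmup_w)]
    for i in range(4):
        phases.append(("interval", HIIT_INTERVAL_S, interval_w))
        if i < 3:
            phases.append(("recovery", HIIT_RECOVERY_S, RECOVERY_POWER_W))
    phases.append(("cooldown", HIIT_COOLDOWN_S, RECOVERY_POWER_W))
    return Prescription(group="HIIT", phases=phases, target_hr=0.90 * hr_max, week=week)


def prescribe_mict(ltp1_po: float, hr_po_slope: float, hr_po_intercept: float,
                   week: int = 1) -> Prescription:
    """60 min of continuous cycling at 90 % of the LTP1 power.

    The target heart rate is the HR–power line evaluated at the prescribed
    power.
    """
    if not ltp1_po > 0:
        raise ValueError(f"ltp1_po must be > 0, got {ltp1_po}")
    power = float(round(0.90 * ltp1_po))
    target_hr = hr_po_intercept + hr_po_slope * power
    return Prescription(group="MICT", phases=[("steady", MICT_DURATION_S, power)],
                        target_hr=float(target_hr), week=week)


# ---------------------------------------------------------------------------
# Weekly monitoring
# ---------------------------------------------------------------------------

def clean_hr(hr, window: int = 31, z: float = 3.0):
    """Remove heart-rate artefacts against a rolling-median MAD band.

    Samples deviating from the centred rolling median by more than
    ``z`` robust standard deviations (1.4826·MAD) are deleted and linearly
    re-interpolated on the 1 Hz grid.  Returns ``(cleaned, removed_mask)``.
    """
    hr = pd.Series(np.asarray(hr, dtype=float))
    med = hr.rolling(window, center=True, min_periods=5).median()
    mad = (hr - med).abs().rolling(window, center=True, min_periods=5).median()
    robust_sd = 1.4826 * mad
    dev = (hr - med).abs()
    bad = ((dev > z * robust_sd) & (robust_sd > 0)).fillna(False).to_numpy()
    t = np.arange(hr.size, dtype=float)
    if bad.all():
        raise ValueError("all heart-rate samples flagged as anomalous")
    cleaned = np.interp(t, t[~bad], hr.to_numpy()[~bad])
    return cleaned, bad


def ensemble_week(sessions: list, window: int = 31, z: float = 3.0,
                  bin_s: float = 5.0) -> pd.DataFrame:
    """Ensemble-average one week of session logs into a 5-s binned HR trace.

    Each session's heart rate is anomaly-cleaned and re-interpolated at
    1 Hz, sessions are aligned on elapsed time (truncated to the shortest),
    averaged pointwise, then averaged into ``bin_s`` bins.  A week is
    expected to hold 3 sessions; fewer are accepted with a warning.
    """
    if not sessions:
        raise ValueError("no sessions to ensemble")
    if len(sessions) < 3:
        warnings.warn(f"ensembling {len(sessions)} session(s); 3 expected per week")
    cleaned = [clean_hr(s["hr_bpm"], window=window, z=z)[0] for s in sessions]
    n = min(len(c) for c in cleaned)
    mean_hr = np.mean([c[:n] for c in cleaned], axis=0)
    k = (np.arange(n) // int(bin_s)).astype(int)
    counts = np.bincount(k).astype(float)
    hr_bin = np.bincount(k, weights=mean_hr) / counts
    return pd.DataFrame({"time_s": bin_s * np.arange(hr_bin.size) + bin_s / 2.0,
                         "hr_bpm": hr_bin})


@dataclass
class WeeklyDecision:
    week: int
    observed_hr: float
    target_hr: float
    action: str                    # increase_5w | hold | flag_recalibration
    next_prescription: Prescription


def adjust_intensity(week_trace: pd.DataFrame, prescription: Prescription,
                     eval_window_s: float = 120.0) -> WeeklyDecision:
    """Compare the weekly ensemble HR with the prescribed band and decide.

    HIIT: the observed HR is the mean of the four intervals' last
    ``eval_window_s`` means.  MICT: the mean over the whole session.  Below
    target − 3 bpm the work rate of the next week rises by 5 W (intervals
    for HIIT, the continuous power for MICT); above target + 3 bpm the
    ergometer is flagged for recalibration; otherwise hold.  The rule is
    one-sided: prescribed power never decreases.
    """
    t = week_trace["time_s"].to_numpy(dtype=float)
    hr = week_trace["hr_bpm"].to_numpy(dtype=float)
    if prescription.group == "HIIT":
        means = []
        for start, end, _ in prescription.phase_windows("interval"):
            mask = (t >= end - eval_window_s) & (t < end)
            if not mask.any():
                raise ValueError("evaluation window not resolvable from the phase plan")
            means.append(hr[mask].mean())
        observed = float(np.mean(means))
    else:
        observed = float(hr[t < prescription.total_duration_s].mean())

    target = prescription.target_hr
    if observed < target - SWD_BPM:
        action = "increase_5w"
    elif observed > target + SWD_BPM:
        action = "flag_recalibration"
    else:
        action = "hold"

    next_phases = []
    for lab, dur, pw in prescription.phases:
        bump = (action == "increase_5w"
                and lab in ("interval", "steady"))
        next_phases.append((lab, dur, pw + ADJUST_STEP_W if bump else pw))
    nxt = replace(prescription, phases=next_phases, week=prescription.week + 1)
    return WeeklyDecision(week=prescription.week, observed_hr=observed,
                          target_hr=target, action=action, next_prescription=nxt)


# ---------------------------------------------------------------------------
# Session load metrics
# ---------------------------------------------------------------------------

@dataclass
class SessionMetrics:
    """Load summary of one session.  Work in kJ, kcal = work / 4.184."""

    total_work_kj: float
    relative_work_kj_kg: float
    total_kcal: float
    relative_kcal_kg: float
    mean_power_w: float
    pct_po_peak: float
    mean_hr: float
    pct_hr_max: float
    pct_hr_reserve: float
    itrimp: float | None = None
    # HIIT: the same power metrics over the high-intensity intervals only
    interval_mean_power_w: float | None = None
    interval_pct_po_peak: float | None = None
    interval_mean_hr: float | None = None
    interval_pct_hr_max: float | None = None
    interval_pct_hr_reserve: float | None = None


def compute_session_metrics(log: pd.DataFrame, po_peak: float, hr_max: float,
                            hr_rest: float, mass: float,
                            prescription: Prescription | None = None,
                            itrimp_weighting: tuple | None = None) -> SessionMetrics:
    """Work, energy, and heart-rate load metrics of one 1 Hz session log.

    Total work is Σ power·∆t (kJ); kcal is total work / 4.184; relative
    values normalise by body mass.  When a HIIT prescription is supplied the
    power/HR metrics are additionally computed over the high-intensity
    intervals only.  ``itrimp_weighting`` (a, b) enables the iTRIMP.
    """
    if len(log) == 0:
        raise ValueError("empty session log")
    if hr_max <= hr_rest:
        raise ValueError(f"hr_max ({hr_max}) must exceed hr_rest ({hr_rest})")

    t = log["time_s"].to_numpy(dtype=float)
    power = log["power_w"].to_numpy(dtype=float)
    hr = log["hr_bpm"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0

    total_work_kj = float(power.sum() * dt / 1000.0)
    total_kcal = total_work_kj / 4.184
    mean_power = float(power.mean())
    mean_hr = float(hr.mean())

    m = SessionMetrics(
        total_work_kj=total_work_kj,
        relative_work_kj_kg=total_work_kj / mass,
        total_kcal=total_kcal,
        relative_kcal_kg=total_kcal / mass,
        mean_power_w=mean_power,
        pct_po_peak=100.0 * mean_power / po_peak,
        mean_hr=mean_hr,
        pct_hr_max=100.0 * mean_hr / hr_max,
        pct_hr_reserve=100.0 * (mean_hr - hr_rest) / (hr_max - hr_rest),
    )
    if itrimp_weighting is not None:
        m.itrimp = compute_itrimp(log, itrimp_weighting, hr_max, hr_rest)

    if prescription is not None and prescription.group == "HIIT":
        mask = np.zeros(t.size, dtype=bool)
        for start, end, _ in prescription.phase_windows("interval"):
            mask |= (t >= start) & (t < end)
        if mask.any():
            ip, ih = float(power[mask].mean()), float(hr[mask].mean())
            m.interval_mean_power_w = ip
            m.interval_pct_po_peak = 100.0 * ip / po_peak
            m.interval_mean_hr = ih
            m.interval_pct_hr_max = 100.0 * ih / hr_max
            m.interval_pct_hr_reserve = 100.0 * (ih - hr_rest) / (hr_max - hr_rest)
    return m


def fit_lactate_weighting(stage_lactate, stage_hr, hr_max: float, hr_rest: float):
    """Individual exponential lactate weighting la = a·e^(b·x).

    ``x`` is the heart-rate-reserve fraction of each incremental-test stage.
    Falls back to the generic constants (0.64, 1.92) when the fit fails or
    yields a non-positive amplitude; returns ``(a, b, used_fallback)``.
    """
    la = np.asarray(stage_lactate, dtype=float)
    hr = np.asarray(stage_hr, dtype=float)
    keep = ~np.isnan(la)
    la, hr = la[keep], hr[keep]
    x = np.clip((hr - hr_rest) / (hr_max - hr_rest), 0.0, 1.0)
    try:
        if la.size < 3 or np.any(la <= 0):
            raise RuntimeError("unfittable lactate-HR relation")
        # log-linear start values, refined by nonlinear least squares
        b0, log_a0 = np.polyfit(x, np.log(la), 1)
        popt, _ = optimize.curve_fit(lambda xx, a, b: a * np.exp(b * xx), x, la,
                                     p0=(np.exp(log_a0), b0), maxfev=5000)
        a, b = float(popt[0]), float(popt[1])
        if a <= 0:
            raise RuntimeError("non-positive weighting amplitude")
        return a, b, False
    except (RuntimeError, TypeError, ValueError):
        warnings.warn("individual lactate weighting unfittable; using generic constants")
        return GENERIC_WEIGHTING[0], GENERIC_WEIGHTING[1], True


def compute_itrimp(log: pd.DataFrame, weighting: tuple, hr_max: float,
                   hr_rest: float, bin_s: float = 5.0) -> float:
    """Individualised training impulse of one session.

    Per ``bin_s`` bin: heart-rate-reserve fraction x = (HR − HRrest) /
    (HRmax − HRrest) clipped to [0, 1]; weight y = a·e^(b·x) from the
    individual exponential lactate fit; iTRIMP = Σ ∆t[min]·x·y.
    """
    a, b = weighting
    if a <= 0:
        raise ValueError(f"weighting amplitude must be > 0, got {a}")
    if hr_max <= hr_rest:
        raise ValueError(f"hr_max ({hr_max}) must exceed hr_rest ({hr_rest})")
    hr = log["hr_bpm"].to_numpy(dtype=float)
    t = log["time_s"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    k = ((t - t[0]) // bin_s).astype(int)
    counts = np.bincount(k).astype(float)
    hr_bin = np.bincount(k, weights=hr) / counts
    x = np.clip((hr_bin - hr_rest) / (hr_max - hr_rest), 0.0, 1.0)
    dt_min = counts * dt / 60.0
    return float(np.sum(dt_min * x * a * np.exp(b * x)))
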