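"""Breath-by-breath CPET cleaning, binning, and maximal-value extraction.

Input is a breath table with columns ``time_s, vo2_ml_min, vco2_ml_min,
ve_l_min, hr_bpm, power_w`` (strictly increasing time, one row per breath)
plus an optional per-stage lactate table ``stage_power_w, lactate_mmol_l``.

Processing follows the standard incremental-test chain: remove breath
outliers against a local rolling band, interpolate to a 1 Hz grid, average
into 30-s bins, and take V̇O₂max as the highest bin mean.  Attainment is the
two-of-three rule: HRmax within 10 bpm of 220 − age, RER > 1.10, peak
lactate ≥ 8 mmol·L⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BREATH_COLUMNS = ("time_s", "vo2_ml_min", "vco2_ml_min", "ve_l_min", "hr_bpm", "power_w")
_BINNABLE = ("vo2_ml_min", "vco2_ml_min", "ve_l_min", "hr_bpm", "power_w")


def validate_breath_table(df: pd.DataFrame) -> None:
    missing = [c for c in ("time_s", "vo2_ml_min") if c not in df.columns]
    if missing:
        raise ValueError(f"breath table missing columns: {missing}")
    t = df["time_s"].to_numpy()
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("time_s must be strictly increasing")
    if np.any(df["vo2_ml_min"].to_numpy() < 0):
        raise ValueError("vo2_ml_min must be non-negative")


def edit_breaths(raw: pd.DataFrame, window: int = 11, z: float = 1.96):
    """Remove V̇O₂ outlier breaths against a centred rolling band.

    A breath is removed when its V̇O₂ deviates from the centred rolling mean
    of ``window`` breaths by more than ``z`` rolling standard deviations
    (z = 1.96 reads the conventional 95 % band).  Single pass; edge breaths
    without a full window are always kept.

    Returns ``(edited, n_removed)`` where ``edited`` is a copy.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    validate_breath_table(raw)
    if len(raw) < window:
        raise ValueError(f"series of {len(raw)} breaths shorter than window {window}")

    vo2 = raw["vo2_ml_min"]
    roll = vo2.rolling(window, center=True, min_periods=window)
    mean, sd = roll.mean(), roll.std(ddof=1)
    dev = (vo2 - mean).abs()
    outlier = (dev > z * sd).fillna(False) & (sd > 0).fillna(False)
    edited = raw.loc[~outlier].reset_index(drop=True)
    return edited, int(outlier.sum())


class BreathOutlierEditor:
    """sklearn-style transformer wrapping :func:`edit_breaths`.

    Parameters
    ----------
    window : odd int, rolling window in breaths.
    z : band half-width in local standard deviations.

    After ``transform``, ``n_removed_`` holds the removal count of the last
    call.
    """

    def __init__(self, window: int = 11, z: float = 1.96):
        self.window = window
        self.z = z

    def get_params(self, deep=True):
        return {"window": self.window, "z": self.z}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        edited, n = edit_breaths(X, window=self.window, z=self.z)
        self.n_removed_ = n
        return edited

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def interpolate_and_bin(edited: pd.DataFrame, bin_s: float = 30.0) -> pd.DataFrame:
    """Linear 1 Hz interpolation followed by non-overlapping ``bin_s`` averages.

    The 1 Hz grid runs from the first to the last breath; bins are anchored
    at the first sample.  A trailing partial bin is kept only when it covers
    at least half a bin (≥ ``bin_s``/2 seconds), preventing a spuriously
    volatile final value.

    Returns one row per bin: ``bin_start_s``, ``bin_mid_s``, ``n_s`` and the
    mean of every breath channel present.
    """
    validate_breath_table(edited)
    if len(edited) < 2:
        raise ValueError("need at least 2 breaths to interpolate")
    if bin_s <= 0:
        raise ValueError(f"bin_s must be > 0, got {bin_s}")

    t = edited["time_s"].to_numpy(dtype=float)
    grid = np.arange(t[0], t[-1] + 1e-9, 1.0)
    cols = [c for c in _BINNABLE if c in edited.columns]
    interp = {c: np.interp(grid, t, edited[c].to_numpy(dtype=float)) for c in cols}

    k = np.floor((grid - grid[0]) / bin_s).astype(int)
    n_bins = k.max() + 1
    counts = np.bincount(k, minlength=n_bins).astype(float)
    out = {"bin_start_s": grid[0] + bin_s * np.arange(n_bins), "n_s": counts}
    for c in cols:
        out[c] = np.bincount(k, weights=interp[c], minlength=n_bins) / counts
    binned = pd.DataFrame(out)
    binned["bin_mid_s"] = binned["bin_start_s"] + bin_s / 2.0

    # drop a trailing partial bin with < bin_s/2 of data
    if counts[-1] < bin_s / 2.0:
        binned = binned.iloc[:-1].reset_index(drop=True)
    return binned


@dataclass
class AttainmentFlags:
    criterion_hr: bool | None
    criterion_rer: bool | None
    criterion_lactate: bool | None
    attained: bool

    def as_dict(self):
        return {"criterion_hr": self.criterion_hr, "criterion_rer": self.criterion_rer,
                "criterion_lactate": self.criterion_lactate, "attained": self.attained}


@dataclass
class CpetSummary:
    """Maximal values of one incremental test."""

    vo2max: float               # mL/min, highest 30-s bin mean
    po_peak: float              # W, power at task failure
    hr_max: float               # bpm, max over the test
    rer_max: float              # max binned VCO2/VO2
    lactate_max: float | None   # mmol/L, max sample (None when no samples)
    attainment: AttainmentFlags | None = None


def compute_maxima(binned: pd.DataFrame, raw: pd.DataFrame,
                   lactate: pd.DataFrame | None = None,
                   age: float | None = None) -> CpetSummary:
    """Extract maximal values from the binned series and the raw test record.

    V̇O₂max is the highest bin mean; peak power is the last power recorded
    (task failure); HRmax the maximum over the whole test; RER the maximum
    binned V̇CO₂/V̇O₂ ratio.  When ``age`` is given, the two-of-three
    attainment rule is evaluated (on the available criteria if lactate is
    missing).
    """
    if binned.empty:
        raise ValueError("binned series is empty (need at least one full bin)")
    vo2max = float(binned["vo2_ml_min"].max())
    po_peak = float(raw["power_w"].iloc[-1]) if "power_w" in raw.columns else float("nan")
    hr_max = float(raw["hr_bpm"].max()) if "hr_bpm" in raw.columns else float("nan")
    rer = binned["vco2_ml_min"] / binned["vo2_ml_min"]
    rer_max = float(rer.max())
    lactate_max = None
    if lactate is not None and len(lactate):
        lactate_max = float(lactate["lactate_mmol_l"].max())
    summary = CpetSummary(vo2max=vo2max, po_peak=po_peak, hr_max=hr_max,
                          rer_max=rer_max, lactate_max=lactate_max)
    if age is not None:
        summary.attainment = check_attainment(summary, age)
    return summary


def check_attainment(summary: CpetSummary, age: float,
                     hr_tolerance: float = 10.0, rer_threshold: float = 1.10,
                     lactate_threshold: float = 8.0) -> AttainmentFlags:
    """Two-of-three V̇O₂max attainment rule.

    Criteria: HRmax within ``hr_tolerance`` bpm of the age-predicted 220 − age;
    maximal RER above ``rer_threshold``; peak lactate of at least
    ``lactate_threshold`` mmol·L⁻¹.  A missing lactate sample leaves that
    criterion out and the rule is evaluated on the remaining two.
    """
    if age <= 0:
        raise ValueError(f"age must be > 0, got {age}")
    crit_hr = bool(abs(summary.hr_max - (220.0 - age)) <= hr_tolerance)
    crit_rer = bool(summary.rer_max > rer_threshold)
    crit_la = None if summary.lactate_max is None else \
        bool(summary.lactate_max >= lactate_threshold)
    n_true = sum(1 for c in (crit_hr, crit_rer, crit_la) if c)
    return AttainmentFlags(criterion_hr=crit_hr, criterion_rer=crit_rer,
                           criterion_lactate=crit_la, attained=n_true >= 2)


def process_cpet(raw: pd.DataFrame, lactate: pd.DataFrame | None = None,
                 age: float | None = None, window: int = 11, z: float = 1.96,
                 bin_s: float = 30.0):
    """Full chain: edit → interpolate/bin → maxima.  Returns (summary, edited, binned)."""
    edited, _ = edit_breaths(raw, window=window, z=z)
    binned = interpolate_and_bin(edited, bin_s=bin_s)
    summary = compute_maxima(binned, edited, lactate=lactate, age=age)
    return summary, edited, binned
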