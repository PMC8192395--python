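"""StO₂ vascular-occlusion-test metrics: baseline, reperfusion slope, AUC.

A trace is a 2 Hz tissue-oxygen-saturation record (``time_s, sto2_pct``)
with marked cuff-inflation and cuff-release times.  The three metrics of the
reperfusion phase are:

* baseline — mean StO₂ over the last two minutes before cuff inflation;
* slope 2 — OLS upslope over the first 10 s after cuff release (the signal
  is linear there, making a simple slope adequate);
* AUC — trapezoidal area of the reperfusion curve above baseline until
  4 min after release (sub-baseline dips clipped to zero by default so they
  cannot cancel hyperaemic overshoot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class NirsTrace:
    """An StO₂ trace with occlusion event marks (times in seconds)."""

    trace: pd.DataFrame            # columns time_s, sto2_pct
    occlusion_start: float
    occlusion_end: float

    def __post_init__(self):
        sto2 = self.trace["sto2_pct"].to_numpy(dtype=float)
        if np.any((sto2 < 0) | (sto2 > 100)):
            raise ValueError("sto2_pct must lie in [0, 100]")
        if not self.occlusion_start < self.occlusion_end:
            raise ValueError("occlusion_start must precede occlusion_end")

    @property
    def time(self):
        return self.trace["time_s"].to_numpy(dtype=float)

    @property
    def sto2(self):
        return self.trace["sto2_pct"].to_numpy(dtype=float)

    def sample_interval(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass
class NirsMetrics:
    baseline: float            # %
    slope2: float              # %/s
    auc: float                 # %*s


def compute_baseline(trace: NirsTrace, window_s: float = 120.0) -> float:
    """Mean StO₂ over the ``window_s`` seconds immediately before occlusion."""
    t, s = trace.time, trace.sto2
    t0 = trace.occlusion_start
    tol = trace.sample_interval()
    if t[0] > t0 - window_s + tol:
        raise ValueError(
            f"need >= {window_s:.0f} s of pre-occlusion data "
            f"(trace starts {t0 - t[0]:.1f} s before occlusion)")
    mask = (t >= t0 - window_s) & (t < t0)
    return float(s[mask].mean())


def compute_reperfusion_slope(trace: NirsTrace, window_s: float = 10.0) -> float:
    """OLS slope of StO₂ on time over the first ``window_s`` s after release.

    The release sample at ``occlusion_end`` is included; the window is
    half-open on the right.
    """
    t, s = trace.time, trace.sto2
    t1 = trace.occlusion_end
    tol = trace.sample_interval()
    if t[-1] < t1 + window_s - tol:
        raise ValueError(f"need >= {window_s:.0f} s of post-release data")
    mask = (t >= t1) & (t < t1 + window_s)
    if mask.sum() < 3:
        raise ValueError("too few samples in the reperfusion-slope window")
    res = sps.linregress(t[mask], s[mask])
    return float(res.slope)


def compute_auc(trace: NirsTrace, baseline: float, window_s: float = 240.0,
                clip_below_baseline: bool = True) -> float:
    """Trapezoidal area of the reperfusion curve above ``baseline``.

    Integrates StO₂ − baseline over [release, release + ``window_s``]
    (endpoint included for quadrature accuracy).  By default negative
    deviations are clipped to zero before integrating; set
    ``clip_below_baseline=False`` for the signed integral.
    """
    t, s = trace.time, trace.sto2
    t1 = trace.occlusion_end
    tol = trace.sample_interval()
    if t[-1] < t1 + window_s - tol:
        raise ValueError(f"need >= {window_s:.0f} s of post-release data")
    mask = (t >= t1) & (t <= t1 + window_s)
    dev = s[mask] - baseline
    if clip_below_baseline:
        dev = np.clip(dev, 0.0, None)
    return float(np.trapezoid(dev, t[mask]))


def compute_nirs_metrics(trace: NirsTrace, baseline_window_s: float = 120.0,
                         slope_window_s: float = 10.0, auc_window_s: float = 240.0,
                         clip_below_baseline: bool = True) -> NirsMetrics:
    """All three vascular-occlusion-test metrics of one trace."""
    baseline = compute_baseline(trace, window_s=baseline_window_s)
    slope2 = compute_reperfusion_slope(trace, window_s=slope_window_s)
    auc = compute_auc(trace, baseline, window_s=auc_window_s,
                      clip_below_baseline=clip_below_baseline)
    return NirsMetrics(baseline=baseline, slope2=slope2, auc=auc)
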