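"""Lactate turning points (LTP1/LTP2) and efficiency slopes.

The lactate–power relation of an incremental test is fitted with a
continuous three-segment piecewise-linear model; the two breakpoints are the
first and second lactate turning points, separating the moderate, heavy and
severe exercise-intensity domains.  Breakpoints are located by exhaustive
grid search (default 1 W grid), which is deterministic and globally optimal
at stage-test problem sizes.

Also provided: per-stage summaries from the breath record, the oxygen uptake
efficiency slope OUES (V̇O₂ = a·log₁₀ V̇E + b), and the ∆V̇O₂/∆PO and
∆HR/∆V̇O₂ least-squares slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def _linregress(x, y, what="regressor"):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 points to fit a line on {what}")
    if np.ptp(x) == 0:
        raise ValueError(f"constant {what}: slope undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def summarize_stages(breath: pd.DataFrame, lactate: pd.DataFrame | None = None,
                     stage_s: float = 180.0, hr_window_s: float = 30.0,
                     vo2_window_s: float = 60.0, min_stages: int = 4,
                     tol_s: float = 8.0) -> pd.DataFrame:
    """Per-completed-stage summaries from a breath record.

    Stages are contiguous constant-positive-power segments of the power
    channel; a stage is completed when it lasts at least ``stage_s`` seconds
    (within ``tol_s``).  Per stage: power, mean HR over the last
    ``hr_window_s``, mean V̇O₂ over the last ``vo2_window_s`` (the steady
    portion of a 3-min stage), and the end-stage lactate sample matched by
    power.  Stages without a lactate sample are flagged
    (``has_lactate=False``) and excluded from the lactate fit downstream.

    Raises when fewer than ``min_stages`` stages complete (two breakpoints
    are unidentifiable below four stages).
    """
    t = breath["time_s"].to_numpy(dtype=float)
    p = breath["power_w"].to_numpy(dtype=float)
    if t.size == 0:
        raise ValueError("empty breath table")

    # contiguous constant-power segments
    change = np.flatnonzero(np.diff(p) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [p.size]])

    la_map = {}
    if lactate is not None:
        for pw, la in zip(lactate["stage_power_w"], lactate["lactate_mmol_l"]):
            la_map[float(pw)] = float(la)

    rows = []
    for s, e in zip(starts, ends):
        power = p[s]
        if power <= 0:
            continue
        t_start, t_end = t[s], t[e - 1]
        if t_end - t_start < stage_s - tol_s:
            continue
        hr_mask = (t >= t_end - hr_window_s) & (t <= t_end) & (p == power)
        vo2_mask = (t >= t_end - vo2_window_s) & (t <= t_end) & (p == power)
        rows.append({
            "power_w": float(power),
            "hr_bpm": float(breath["hr_bpm"].to_numpy()[hr_mask].mean()),
            "vo2_ml_min": float(breath["vo2_ml_min"].to_numpy()[vo2_mask].mean()),
            "lactate_mmol_l": la_map.get(float(power), np.nan),
        })
    stages = pd.DataFrame(rows)
    if len(stages) < min_stages:
        raise ValueError(
            f"only {len(stages)} completed stages; need >= {min_stages} for a "
            "two-breakpoint lactate fit")
    stages["has_lactate"] = stages["lactate_mmol_l"].notna()
    return stages


@dataclass
class ThresholdFit:
    """Two-breakpoint piecewise-linear lactate fit and its V̇O₂ mappings."""

    ltp1_po: float
    ltp2_po: float
    slopes: tuple                      # (s1, s2, s3), mmol/L per W
    intercepts: tuple                  # per-segment intercepts (continuity holds)
    sse: float
    vo2_at_ltp1: float | None = None
    vo2_at_ltp2: float | None = None
    hr_at_ltp1: float | None = None
    hr_at_ltp2: float | None = None

    def predict(self, power):
        p = np.asarray(power, dtype=float)
        s1, s2, s3 = self.slopes
        c0 = self.intercepts[0]
        y = (c0 + s1 * np.minimum(p, self.ltp1_po)
             + s2 * np.clip(np.minimum(p, self.ltp2_po) - self.ltp1_po, 0.0, None)
             + s3 * np.clip(p - self.ltp2_po, 0.0, None))
        return y if y.ndim else float(y)


class SegmentedLactateModel:
    """Continuous 3-segment piecewise-linear least squares with grid-searched breakpoints.

    The model is ``la(p) = c0 + c1·p + c2·(p − b1)⁺ + c3·(p − b2)⁺`` — the
    hinge parameterisation is continuous at both breakpoints by construction.
    Candidate pairs ``b1 < b2`` lie on a ``grid_step``-W grid strictly inside
    (min power, max power), constrained to keep at least one observation in
    each outer segment; for each pair the linear coefficients are solved in
    closed form and the global SSE minimiser is returned.  Ties are broken by
    the smaller ``b1``, then smaller ``b2``.

    Fitted attributes: ``ltp1_po_``, ``ltp2_po_``, ``slopes_``, ``sse_``,
    ``fit_`` (a :class:`ThresholdFit`).
    """

    def __init__(self, grid_step: float = 1.0, include_baseline_at_zero: bool = False):
        self.grid_step = grid_step
        self.include_baseline_at_zero = include_baseline_at_zero

    def get_params(self, deep=True):
        return {"grid_step": self.grid_step,
                "include_baseline_at_zero": self.include_baseline_at_zero}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, power, lactate):
        p = np.asarray(power, dtype=float)
        y = np.asarray(lactate, dtype=float)
        keep = ~np.isnan(y)
        p, y = p[keep], y[keep]
        if p.size < 4:
            raise ValueError(f"need >= 4 stages with lactate, got {p.size}")
        if np.ptp(y) == 0:
            raise ValueError("no identifiable breakpoints: lactate is constant")

        step = self.grid_step
        lo = np.floor(p.min() / step) * step + step
        hi = np.ceil(p.max() / step) * step - step
        grid = np.arange(lo, hi + step / 2, step)
        # candidate breakpoints must leave >= 1 stage in each outer segment
        g1 = grid[np.array([(p < b).sum() >= 1 for b in grid])]
        g2 = grid[np.array([(p > b).sum() >= 1 for b in grid])]
        b1, b2 = np.meshgrid(g1, g2, indexing="ij")
        mask = b1 < b2
        b1, b2 = b1[mask], b2[mask]
        # lexicographic order (b1 asc, then b2 asc) so argmin tie-breaks low
        order = np.lexsort((b2, b1))
        b1, b2 = b1[order], b2[order]

        # batched least squares over all candidate pairs
        n = p.size
        A = np.empty((b1.size, n, 4))
        A[:, :, 0] = 1.0
        A[:, :, 1] = p
        A[:, :, 2] = np.clip(p[None, :] - b1[:, None], 0.0, None)
        A[:, :, 3] = np.clip(p[None, :] - b2[:, None], 0.0, None)
        G = np.einsum("kni,knj->kij", A, A)
        c = np.einsum("kni,n->ki", A, y)
        coef = np.einsum("kij,kj->ki", np.linalg.pinv(G), c)
        resid = np.einsum("kni,ki->kn", A, coef) - y
        sse = np.einsum("kn,kn->k", resid, resid)

        best = int(np.flatnonzero(sse <= sse.min() + 1e-10)[0])
        c0, c1, c2, c3 = coef[best]
        s = (c1, c1 + c2, c1 + c2 + c3)
        bb1, bb2 = float(b1[best]), float(b2[best])
        intercepts = (float(c0),
                      float(c0 - c2 * bb1),
                      float(c0 - c2 * bb1 - c3 * bb2))

        self.ltp1_po_ = bb1
        self.ltp2_po_ = bb2
        self.slopes_ = tuple(float(v) for v in s)
        self.sse_ = float(max(sse[best], 0.0))
        self.fit_ = ThresholdFit(ltp1_po=bb1, ltp2_po=bb2, slopes=self.slopes_,
                                 intercepts=intercepts, sse=self.sse_)
        return self

    def predict(self, power):
        if not hasattr(self, "fit_"):
            raise ValueError("model is not fitted")
        return self.fit_.predict(power)


def fit_two_breakpoint(stages: pd.DataFrame, grid_step: float = 1.0,
                       baseline_lactate: float | None = None) -> ThresholdFit:
    """Fit LTP1/LTP2 from a stage-summary table (see :func:`summarize_stages`).

    ``baseline_lactate`` optionally adds the resting sample as a pseudo-stage
    at 0 W (an honest extra point on the first segment).
    """
    sub = stages[stages["has_lactate"]] if "has_lactate" in stages.columns else stages
    p = sub["power_w"].to_numpy(dtype=float)
    y = sub["lactate_mmol_l"].to_numpy(dtype=float)
    if baseline_lactate is not None:
        p = np.concatenate([[0.0], p])
        y = np.concatenate([[baseline_lactate], y])
    model = SegmentedLactateModel(grid_step=grid_step)
    model.fit(p, y)
    return model.fit_


def map_thresholds_to_vo2(fit: ThresholdFit, stages: pd.DataFrame) -> ThresholdFit:
    """Map LTP powers to V̇O₂ (and HR) via the stage-wise linear relations.

    An ordinary least-squares line of stage V̇O₂ on stage power is evaluated
    at both breakpoints; the analogous HR line provides the threshold heart
    rates used for training prescription.
    """
    slope, intercept, _ = _linregress(stages["power_w"], stages["vo2_ml_min"],
                                      what="stage power")
    fit.vo2_at_ltp1 = slope * fit.ltp1_po + intercept
    fit.vo2_at_ltp2 = slope * fit.ltp2_po + intercept
    if "hr_bpm" in stages.columns:
        hs, hi, _ = _linregress(stages["power_w"], stages["hr_bpm"], what="stage power")
        fit.hr_at_ltp1 = hs * fit.ltp1_po + hi
        fit.hr_at_ltp2 = hs * fit.ltp2_po + hi
    return fit


@dataclass
class SlopeSet:
    """Efficiency slopes of one incremental test."""

    oues_a: float               # mL/min per log10(L/min)
    oues_b: float               # mL/min
    oues_r2: float
    dvo2_dpo: float             # mL/min per W
    dvo2_dpo_r2: float
    dhr_dvo2: float             # bpm per mL/min
    dhr_dvo2_r2: float


def fit_oues(binned_exercise: pd.DataFrame):
    """OUES: OLS of V̇O₂ (mL/min) on log₁₀ V̇E over the exercise phase.

    Returns ``(a, b, r²)`` of V̇O₂ = a·log₁₀(V̇E) + b.  V̇E must be strictly
    positive throughout.
    """
    ve = binned_exercise["ve_l_min"].to_numpy(dtype=float)
    if np.any(ve <= 0):
        raise ValueError("non-positive VE in the OUES window")
    return _linregress(np.log10(ve), binned_exercise["vo2_ml_min"], what="log10 VE")


def fit_linear_slopes(df: pd.DataFrame):
    """∆V̇O₂/∆PO and ∆HR/∆V̇O₂ least-squares slopes on exercise-phase data.

    Returns ``(dvo2_dpo, r², dhr_dvo2, r²)``.
    """
    s1, _, r1 = _linregress(df["power_w"], df["vo2_ml_min"], what="power")
    s2, _, r2 = _linregress(df["vo2_ml_min"], df["hr_bpm"], what="VO2")
    return s1, r1, s2, r2


def compute_slopes(binned: pd.DataFrame) -> SlopeSet:
    """All three efficiency slopes from a 30-s binned exercise-phase series."""
    exercise = binned[binned["power_w"] > 0]
    a, b, r2_oues = fit_oues(exercise)
    dvo2_dpo, r2_po, dhr_dvo2, r2_hr = fit_linear_slopes(exercise)
    return SlopeSet(oues_a=a, oues_b=b, oues_r2=r2_oues,
                    dvo2_dpo=dvo2_dpo, dvo2_dpo_r2=r2_po,
                    dhr_dvo2=dhr_dvo2, dhr_dvo2_r2=r2_hr)
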