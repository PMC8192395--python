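"""Group-comparison statistics reconstructible from printed summaries.

Welch's unequal-variance t-test and Cohen's d with a confidence interval,
computed from (n, mean, sd) summaries alone — the two quantities that can be
reproduced exactly from a published table without the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    """Summary statistics of one group (any consistent unit)."""

    n: int
    mean: float
    sd: float

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_test(a: GroupSummary, b: GroupSummary) -> WelchResult:
    """Welch's two-sample t-test from group summaries.

    Returns the t statistic, Welch–Satterthwaite degrees of freedom, and the
    two-sided p value.
    """
    a.validate()
    b.validate()
    if a.sd == 0 and b.sd == 0:
        raise ValueError("Welch test undefined: both groups have zero variance")
    t, p = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                    equal_var=False)
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return WelchResult(t=float(t), df=float(df), p=float(p))


def cohens_d_ci(a: GroupSummary, b: GroupSummary, level: float = 0.95,
                denominator: str = "rms", ci: str = "normal"):
    """Cohen's d between two groups with a confidence interval.

    The default denominator is the root mean square of the two SDs,
    d = (mean_a − mean_b) / √((sd_a² + sd_b²)/2); ``denominator="pooled"``
    uses the df-weighted pooled SD.  The CI is d ± z·SE with
    SE = √((n_a+n_b)/(n_a·n_b) + d²/(2(n_a+n_b−2))) and z the standard
    normal quantile (``ci="t"`` substitutes the t quantile at Welch df).

    Returns ``(d, (lo, hi))``.
    """
    a.validate()
    b.validate()
    if denominator == "rms":
        s = np.sqrt((a.sd ** 2 + b.sd ** 2) / 2.0)
    elif denominator == "pooled":
        s = np.sqrt(((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2)
                    / (a.n + b.n - 2))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if s == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    d = (a.mean - b.mean) / s
    se = np.sqrt((a.n + b.n) / (a.n * b.n) + d ** 2 / (2.0 * (a.n + b.n - 2)))
    if ci == "normal":
        q = sps.norm.ppf(0.5 + level / 2.0)
    elif ci == "t":
        q = sps.t.ppf(0.5 + level / 2.0, welch_test(a, b).df)
    else:
        raise ValueError(f"unknown ci {ci!r}")
    return float(d), (float(d - q * se), float(d + q * se))
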