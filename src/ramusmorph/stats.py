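"""Reliability and accuracy statistics.

Interobserver agreement is summarised per region and method by the
single-measure one-way random-effects intraclass correlation ICC(1,1) with
its exact F-based 95% confidence interval, and by the mean absolute
difference (MAD) with the standard deviation of the absolute differences.
Method comparisons use the classical paired t-test.

For n subjects rated by k raters, one-way ANOVA gives the between-subject
(MSB) and within-subject (MSW) mean squares and

    ICC(1,1) = (MSB - MSW) / (MSB + (k - 1) MSW)

with confidence bounds from F = MSB/MSW against the F(n-1, n(k-1))
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "icc_oneway_single",
    "mad_sd",
    "paired_t",
    "classify_icc",
    "ICCResult",
    "PairedMeasurements",
    "reliability_table",
    "DEFAULT_ICC_THRESHOLDS",
]

#: conventional single-measure ICC interpretation bands
DEFAULT_ICC_THRESHOLDS = {"poor": 0.5, "moderate": 0.75, "good": 0.9}


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    degenerate: bool = False  # all ratings identical: ICC 1 by convention


def icc_oneway_single(observer1, observer2, *more, confidence: float = 0.95) -> ICCResult:
    """ICC(1,1): one-way random effects, absolute agreement, single measures.

    Accepts two (or more) index-aligned rater arrays.  Raises on fewer than
    two subjects.  If every rating is identical the estimate is 1 by
    convention with a degenerate (flagged) confidence interval.
    """
    ratings = np.column_stack([observer1, observer2, *more]).astype(float)
    n, k = ratings.shape
    if n < 2:
        raise ValueError(f"ICC needs >= 2 subjects, got {n}")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings contain non-finite values")

    grand = ratings.mean()
    subject_means = ratings.mean(axis=1)
    ss_between = k * np.sum((subject_means - grand) ** 2)
    ss_within = np.sum((ratings - subject_means[:, None]) ** 2)
    df_b, df_w = n - 1, n * (k - 1)
    msb = ss_between / df_b
    msw = ss_within / df_w

    if msw == 0.0:
        if msb == 0.0:
            raise ValueError("all ratings identical across subjects: ICC undefined")
        return ICCResult(1.0, 1.0, 1.0, n, k, degenerate=True)

    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_obs = msb / msw
    alpha = 1.0 - confidence
    f_upper = sps.f.ppf(1 - alpha / 2, df_b, df_w)
    f_lower = sps.f.ppf(1 - alpha / 2, df_w, df_b)
    fl = f_obs / f_upper
    fu = f_obs * f_lower
    ci_low = (fl - 1.0) / (fl + k - 1.0)
    ci_high = (fu - 1.0) / (fu + k - 1.0)
    return ICCResult(float(icc), float(ci_low), float(ci_high), n, k)


def mad_sd(observer1, observer2):
    """Mean absolute difference and its standard deviation (n-1 denominator).

    With a single pair the SD is reported as 0."""
    a = np.asarray(observer1, dtype=float)
    b = np.asarray(observer2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("need at least one pair")
    d = np.abs(a - b)
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd


def paired_t(values_a, values_b):
    """Classical two-sided paired t-test on index-aligned samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must be index-aligned")
    if a.size < 2:
        raise ValueError(f"paired t needs n >= 2, got {a.size}")
    if np.var(a - b, ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t is degenerate")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def classify_icc(icc: float, thresholds: dict | None = None) -> str:
    """Reliability label for an ICC estimate (default bands: < 0.5 poor,
    0.5-0.75 moderate, 0.75-0.9 good, > 0.9 excellent)."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    th = thresholds or DEFAULT_ICC_THRESHOLDS
    if icc < th["poor"]:
        return "poor"
    if icc < th["moderate"]:
        return "moderate"
    if icc < th["good"]:
        return "good"
    return "excellent"


@dataclass
class PairedMeasurements:
    """Index-aligned per-ramus values of one quantity from two observers."""

    region: str
    method: str  # {"surface", "voxel"}
    quantity: str  # {"volume_pct", "distance_mm"}
    observer1: np.ndarray
    observer2: np.ndarray

    def __post_init__(self):
        self.observer1 = np.asarray(self.observer1, dtype=float)
        self.observer2 = np.asarray(self.observer2, dtype=float)
        if self.observer1.shape != self.observer2.shape:
            raise ValueError("observer arrays must be index-aligned")


def reliability_table(measurements: list[PairedMeasurements]) -> pd.DataFrame:
    """Per region x method x quantity reliability summary (the machine twin of
    a per-region supplementary table)."""
    rows = []
    for pm in measurements:
        icc = icc_oneway_single(pm.observer1, pm.observer2)
        mad, sd = mad_sd(pm.observer1, pm.observer2)
        rows.append(
            {
                "region": pm.region,
                "method": pm.method,
                "quantity": pm.quantity,
                "icc": icc.icc,
                "ci_low": icc.ci_low,
                "ci_high": icc.ci_high,
                "mad": mad,
                "sd": sd,
                "n": len(pm.observer1),
                "classification": classify_icc(icc.icc),
            }
        )
    return pd.DataFrame(rows)
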