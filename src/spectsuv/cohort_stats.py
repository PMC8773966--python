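"""Cohort-level statistics for SUVmax discrimination of bone lesions.

Implements the analysis chain used to separate metastatic from degenerative
bone lesions on SUVmax: descriptive summaries, Shapiro-Wilk normality,
the Mann-Whitney U test (asymptotic with midrank-tie correction, plus an
exact-enumeration oracle for tiny samples), the empirical ROC curve with
its U-statistic identity AUC, a DeLong 95% confidence interval, the Youden
optimal cut-off under the strict "positive if SUVmax > t" rule, and the
overlap/bin breakdowns used to describe how the two lesion populations
intermix.

Conventions: metastatic is the positive class; sensitivity is the fraction
of metastatic lesions above threshold, specificity the fraction of
degenerative lesions at or below it.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "RocCurve",
    "CutoffResult",
    "BinBreakdown",
    "summarize",
    "region_distribution",
    "shapiro_wilk",
    "mann_whitney",
    "empirical_roc",
    "auc_ci",
    "youden_cutoff",
    "bin_breakdown",
    "overlap_range",
]

REGIONS = ("L", "T", "P", "O")

#: SUVmax bin edges (g/mL) used in the overlap breakdown; a value exactly
#: on an edge falls in the upper bin.
BIN_EDGES = (20.0, 27.0)


@dataclass(frozen=True)
class SummaryStats:
    n: int
    min: float
    max: float
    mean: float
    sd: float


@dataclass
class RocCurve:
    """Empirical ROC under the rule "positive if score > threshold".

    ``thresholds`` are the distinct observed scores in ascending order,
    preceded by -inf (the classify-everything-positive endpoint).
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class BinBreakdown:
    """Counts/percentages in [min, 20), [20, 27) and [27, inf) g/mL."""

    counts: tuple[int, int, int]
    percentages: tuple[float, float, float]
    n: int


def summarize(values) -> SummaryStats:
    """n, min, max, mean and sample sd (n-1 denominator; 0 for n = 1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return SummaryStats(n=int(v.size), min=float(v.min()), max=float(v.max()),
                        mean=float(v.mean()), sd=sd)


def region_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Lesion counts and percentages per anatomical region.

    Regions are L (lumbar), T (thoracic), P (pelvic), O (other).
    Percentages are rounded to 2 decimals.
    """
    regions = table["region"]
    bad = ~regions.isin(REGIONS)
    if bad.any():
        row = table.index[bad][0]
        raise ValueError(
            f"unknown region code {regions[row]!r} in row {row}")
    counts = regions.value_counts().reindex(REGIONS, fill_value=0)
    total = int(counts.sum())
    pct = (counts / total * 100).round(2)
    return pd.DataFrame({"count": counts.astype(int), "percent": pct})


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (Royston algorithm via scipy)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for sample x with midrank ties."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2)


def _exact_mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by exhaustive enumeration of group assignments.

    Enumerates every way of labelling the pooled sample, computing U on the
    shared midranks; feasible for n_x + n_y <= ~14.
    """
    n_x, n = x.size, x.size + y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = _u_statistic(x, y)
    mean_u = x.size * y.size / 2.0
    dev_obs = abs(u_obs - mean_u)
    hits = total = 0
    offset = n_x * (n_x + 1) / 2
    for combo in itertools.combinations(range(n), n_x):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(x, y, method: str = "asymptotic") -> tuple[float, float]:
    """Mann-Whitney U (for sample x) and two-sided p-value.

    ``method='asymptotic'`` uses the normal approximation with midrank-tie
    variance correction and continuity correction (standard for the cohort
    sizes here); ``method='exact'`` enumerates all group assignments and is
    intended for tiny samples (n_x + n_y <= 14).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if method == "exact":
        return u, _exact_mann_whitney_p(x, y)
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tie warning on constant data
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return u, float(res.pvalue)


def _check_two_classes(scores: np.ndarray, labels: np.ndarray) -> None:
    if not (labels.any() and (~labels).any()):
        raise ValueError("both classes must be present")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")


def empirical_roc(scores, labels) -> RocCurve:
    """Empirical ROC curve; metastatic (label truthy) is positive.

    Thresholds are the distinct observed scores plus a -inf endpoint; the
    decision rule is strict ("positive if score > t").  The trapezoidal
    AUC equals U / (n_pos * n_neg) of the Mann-Whitney statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(scores, labels)
    pos = scores[labels]
    neg = scores[~labels]
    thresholds = np.concatenate([[-np.inf], np.unique(scores)])
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    # integrate TPR over FPR; thresholds ascend so FPR = 1 - spec descends
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return RocCurve(thresholds=thresholds, sens=sens, spec=spec, auc=auc)


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong variance of the empirical AUC via placement values."""
    v_pos = np.array([( (p > neg).mean() + 0.5 * (p == neg).mean() )
                      for p in pos])
    v_neg = np.array([( (pos > n).mean() + 0.5 * (pos == n).mean() )
                      for n in neg])
    s_pos = np.var(v_pos, ddof=1) if pos.size > 1 else 0.0
    s_neg = np.var(v_neg, ddof=1) if neg.size > 1 else 0.0
    return s_pos / pos.size + s_neg / neg.size


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-theory confidence interval for the AUC, clipped to [0,1].

    Degenerate separation (AUC of 0 or 1 with zero variance) yields a point
    interval and a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(scores, labels)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each class needs n >= 2 for a variance estimate")
    pos, neg = scores[labels], scores[~labels]
    auc = empirical_roc(scores, labels).auc
    var = _delong_variance(pos, neg, auc)
    if var <= 0:
        warnings.warn("degenerate AUC variance; returning point interval")
        return auc, auc
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def youden_cutoff(roc: RocCurve) -> CutoffResult:
    """Threshold maximizing Youden's J = sens + spec - 1.

    Ties are broken toward the smallest threshold.  The -inf endpoint is
    never reported: the smallest finite candidate wins ties with it
    whenever J is maximal there too (at -inf, J = 0).
    """
    j = roc.sens + roc.spec - 1.0
    finite = np.isfinite(roc.thresholds)
    j_max = j.max()
    candidates = np.flatnonzero((j >= j_max - 1e-12) & finite)
    idx = candidates[0] if candidates.size else int(np.argmax(j))
    return CutoffResult(threshold=float(roc.thresholds[idx]),
                        sensitivity=float(roc.sens[idx]),
                        specificity=float(roc.spec[idx]))


def bin_breakdown(values, edges: tuple[float, float] = BIN_EDGES
                  ) -> BinBreakdown:
    """Counts and percentages in [min, e1), [e1, e2), [e2, inf).

    A value exactly on an edge belongs to the upper bin (so an SUVmax of
    exactly 27.00 counts as "27.00 or above").  Percentages to 1 decimal.
    """
    v = np.asarray(values, dtype=float)
    e1, e2 = edges
    low = int((v < e1).sum())
    mid = int(((v >= e1) & (v < e2)).sum())
    high = int((v >= e2).sum())
    n = int(v.size)
    pct = tuple(round(c / n * 100, 1) if n else 0.0
                for c in (low, mid, high))
    return BinBreakdown(counts=(low, mid, high), percentages=pct, n=n)


def overlap_range(met_values, deg_values
                  ) -> tuple[tuple[float, float] | None, int, float]:
    """Overlap interval [min(met), max(deg)] and how many values fall in it.

    Returns (interval or None if empty, count inside over both samples,
    fraction of all values inside); the interval is closed.
    """
    met = np.asarray(met_values, dtype=float)
    deg = np.asarray(deg_values, dtype=float)
    if met.size == 0 or deg.size == 0:
        raise ValueError("both samples must be non-empty")
    lo, hi = float(met.min()), float(deg.max())
    if lo > hi:
        return None, 0, 0.0
    allv = np.concatenate([met, deg])
    inside = int(((allv >= lo) & (allv <= hi)).sum())
    return (lo, hi), inside, inside / allv.size
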