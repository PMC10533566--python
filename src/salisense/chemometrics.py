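"""Statistics of the sensor study.

The univariate toolkit used throughout: Euclidean-norm total response, the
discrimination ability function (DAF, the between/within variance ratio used
to rank fabrication conditions), pooled/Welch two-sample t-tests, Pearson
correlation, replicate RSD%, confusion-matrix metrics, and the grand-mean
threshold rule on total responses — the latter also packaged as a
scikit-learn style classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from ._util import round_half_away
from .panel import DIABETIC, NONDIABETIC


# --------------------------------------------------------------------------
# total response

def euclidean_norm(vector) -> float:
    """Total response of one sample: sqrt of the sum of squared features."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("expected a non-empty 1-D vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("vector contains non-finite entries")
    return float(np.linalg.norm(v))


def row_norms(matrix) -> np.ndarray:
    """Euclidean norm of every row of an n x p response matrix."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("expected a 2-D matrix with at least one column")
    return np.linalg.norm(X, axis=1)


# --------------------------------------------------------------------------
# DAF — discrimination ability function

@dataclass(frozen=True)
class DAFResult:
    """Separation score of one experimental condition."""

    condition_id: str
    daf: float
    groups: Tuple[str, ...]
    n_per_group: Tuple[int, ...]


def daf(values, labels) -> float:
    """Between-group over within-group variance ratio.

    For scalar responses this is exactly the one-way ANOVA F statistic
    (MSB/MSW).  For vector responses the trace of the between-group scatter
    over the trace of the within-group scatter is used, with the same
    (k-1, n-k) degree-of-freedom normalisation.  Zero iff all group means
    coincide; ``inf`` when groups are perfectly tight but separated.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("values and labels length mismatch")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    counts = np.array([(labels == g).sum() for g in uniq])
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    n, k = X.shape[0], uniq.size
    grand = X.mean(axis=0)
    ssb = 0.0
    ssw = 0.0
    for g, ng in zip(uniq, counts):
        block = X[labels == g]
        mu = block.mean(axis=0)
        ssb += ng * float(np.sum((mu - grand) ** 2))
        ssw += float(np.sum((block - mu) ** 2))
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    if msw == 0.0:
        return 0.0 if msb == 0.0 else math.inf
    return msb / msw


def rank_conditions(conditions: Mapping[str, Sequence], labels) -> list:
    """Score each condition by DAF and sort best-first.

    ``conditions`` maps a condition id to the per-sample responses measured
    under that condition; ``labels`` gives the shared group assignment.
    Ties (equal DAF) break lexicographically on the condition id, so the
    ordering is deterministic.
    """
    if len(conditions) < 1:
        raise ValueError("need at least one condition")
    labels = np.asarray(labels)
    uniq = tuple(np.unique(labels))
    counts = tuple(int((labels == g).sum()) for g in uniq)
    results = [
        DAFResult(str(cid), daf(vals, labels), uniq, counts)
        for cid, vals in conditions.items()
    ]
    return sorted(results, key=lambda r: (-r.daf, r.condition_id))


# --------------------------------------------------------------------------
# t-test

@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    variant: str


def two_sample_ttest(mean1: float, sd1: float, n1: int,
                     mean2: float, sd2: float, n2: int,
                     variant: str = "pooled") -> TTestResult:
    """Two-independent-sample t-test from group summaries.

    ``pooled`` (Student, equal variances assumed) by default; ``welch``
    available.  Degenerate zero-variance inputs return t = 0, p = 1 when the
    means agree and an infinite t (p = 0) when they differ.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if sd1 == 0.0 and sd2 == 0.0:
        if mean1 == mean2:
            return TTestResult(0.0, 1.0, float(n1 + n2 - 2), variant)
        return TTestResult(math.copysign(math.inf, mean1 - mean2), 0.0,
                           float(n1 + n2 - 2), variant)
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        a, b = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))
    return TTestResult(float(t), float(p), df, variant)


def two_sample_ttest_samples(x, y, variant: str = "pooled") -> TTestResult:
    """Same test from raw samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_ttest(float(x.mean()), float(x.std(ddof=1)), x.size,
                            float(y.mean()), float(y.std(ddof=1)), y.size,
                            variant=variant)


# --------------------------------------------------------------------------
# Pearson correlation and RSD

@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Sample Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for a constant input")
    res = stats.pearsonr(x, y)
    return PearsonResult(float(res.statistic), float(res.pvalue), int(x.size))


def rsd_percent(values) -> float:
    """Relative standard deviation, 100 * sample SD (ddof=1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("RSD needs at least two replicate values")
    mean = v.mean()
    if mean == 0.0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def fbg_bin_midpoints(fbg, edges: Sequence[float], top_value: float) -> np.ndarray:
    """Map FBG values to the midpoint of their right-open category.

    ``edges`` are the finite left edges ([0, 100, 126, 200) by default);
    values at or above the last edge map to ``top_value``.
    """
    fbg = np.asarray(fbg, dtype=float)
    edges = np.asarray(edges, dtype=float)
    mids = np.append((edges[:-1] + edges[1:]) / 2.0, top_value)
    idx = np.clip(np.searchsorted(edges, fbg, side="right") - 1, 0, mids.size - 1)
    return mids[idx]


# --------------------------------------------------------------------------
# threshold rule on total responses

def threshold_classify(norms, threshold: float) -> np.ndarray:
    """Grand-mean rule: total response above the threshold reads diabetic.

    Ties (norm exactly equal to the threshold) go to non-diabetic — the rule
    is strictly "greater than".
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    norms = np.asarray(norms, dtype=float)
    return np.where(norms > threshold, DIABETIC, NONDIABETIC)


@dataclass(frozen=True)
class TotalResponseSummary:
    """Norm statistics of one analysed dataset."""

    norms: np.ndarray
    mean_d: float
    sd_d: float
    n_d: int
    mean_nd: float
    sd_nd: float
    n_nd: int
    grand_mean: float
    mean_difference: float
    ttest: TTestResult


def total_response_summary(matrix, labels, variant: str = "pooled") -> TotalResponseSummary:
    """Group norm means/SDs, grand mean, and the two-sample t-test."""
    norms = row_norms(matrix)
    labels = np.asarray(labels)
    d = norms[labels == DIABETIC]
    nd = norms[labels == NONDIABETIC]
    if d.size < 2 or nd.size < 2:
        raise ValueError("both groups need at least two samples")
    test = two_sample_ttest_samples(d, nd, variant=variant)
    return TotalResponseSummary(
        norms=norms,
        mean_d=float(d.mean()), sd_d=float(d.std(ddof=1)), n_d=int(d.size),
        mean_nd=float(nd.mean()), sd_nd=float(nd.std(ddof=1)), n_nd=int(nd.size),
        grand_mean=float(norms.mean()),
        mean_difference=float(d.mean() - nd.mean()),
        ttest=test,
    )


class NormThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Univariate diagnostic rule on the total response.

    Parameters
    ----------
    threshold : float, optional
        Fixed decision threshold.  When None (default) the threshold is the
        grand mean of the training norms (the grand-mean rule).

    Attributes
    ----------
    threshold_ : fitted decision threshold.
    classes_ : ``['diabetic', 'nondiabetic']``.
    """

    def __init__(self, threshold: Optional[float] = None):
        self.threshold = threshold

    def fit(self, X, y=None):
        norms = row_norms(np.atleast_2d(np.asarray(X, dtype=float)))
        self.threshold_ = float(norms.mean()) if self.threshold is None else float(self.threshold)
        self.classes_ = np.array([DIABETIC, NONDIABETIC])
        return self

    def decision_function(self, X):
        norms = row_norms(np.atleast_2d(np.asarray(X, dtype=float)))
        return norms - self.threshold_

    def predict(self, X):
        norms = row_norms(np.atleast_2d(np.asarray(X, dtype=float)))
        return threshold_classify(norms, self.threshold_)


# --------------------------------------------------------------------------
# confusion metrics

@dataclass(frozen=True)
class ClassificationReport:
    """2x2 confusion counts (rows truth, cols predicted; diabetic first)
    with the derived rates in percent (unrounded)."""

    confusion: np.ndarray
    accuracy: float
    error_rate: float
    sensitivity: Dict[str, float] = field(default_factory=dict)
    specificity: Dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    def rounded(self, ndigits: int = 1) -> dict:
        """Reporting-layer view: percentages rounded half away from zero."""
        rnd = lambda v: None if v is None else round_half_away(v, ndigits)
        return {
            "accuracy": rnd(self.accuracy),
            "error_rate": rnd(self.error_rate),
            "sensitivity": {k: rnd(v) for k, v in self.sensitivity.items()},
            "specificity": {k: rnd(v) for k, v in self.specificity.items()},
        }


def confusion_counts(y_true, y_pred) -> np.ndarray:
    """2x2 counts with rows/cols ordered (diabetic, nondiabetic)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    order = (DIABETIC, NONDIABETIC)
    out = np.zeros((2, 2), dtype=int)
    for i, t in enumerate(order):
        for j, p in enumerate(order):
            out[i, j] = int(np.sum((y_true == t) & (y_pred == p)))
    return out


def confusion_metrics(confusion) -> ClassificationReport:
    """Accuracy, error rate and per-class sensitivity/specificity (percent).

    In the two-class setting the specificity of one class equals the
    sensitivity of the other, which is why the table is symmetric.
    """
    c = np.asarray(confusion)
    if c.shape != (2, 2) or (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
        raise ValueError("confusion must be a 2x2 table of non-negative integer counts")
    n = int(c.sum())
    if n == 0:
        raise ValueError("confusion table is empty")
    accuracy = 100.0 * (c[0, 0] + c[1, 1]) / n
    order = (DIABETIC, NONDIABETIC)
    sens = {}
    for i, cls in enumerate(order):
        row = c[i].sum()
        sens[cls] = 100.0 * c[i, i] / row if row > 0 else None
    spec = {order[0]: sens[order[1]], order[1]: sens[order[0]]}
    return ClassificationReport(
        confusion=c,
        accuracy=accuracy,
        error_rate=100.0 - accuracy,
        sensitivity=sens,
        specificity=spec,
    )
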