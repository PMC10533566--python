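"""Norms, DAF, t-tests, Pearson, RSD, confusion metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from salisense import (confusion_metrics, daf, euclidean_norm, pearson,
                       rank_conditions, rsd_percent, threshold_classify,
                       two_sample_ttest, two_sample_ttest_samples)
from salisense.chemometrics import (NormThresholdClassifier, confusion_counts,
                                    fbg_bin_midpoints, total_response_summary)


# ---------------------------------------------------------------- norms

def test_euclidean_norm_basic_cases(rng):
    assert euclidean_norm(np.zeros(36)) == 0.0
    v = np.zeros(36)
    v[0], v[1] = 3.0, 4.0
    assert euclidean_norm(v) == pytest.approx(5.0)
    x = rng.normal(size=100)
    brute = math.sqrt(sum(float(e) ** 2 for e in x))  # independent summation
    assert euclidean_norm(x) == pytest.approx(brute, rel=1e-12)
    with pytest.raises(ValueError):
        euclidean_norm([])


# ---------------------------------------------------------------- DAF

def test_daf_hand_anova_oracle():
    """{1,2,3} vs {7,8,9}: SSB = 54 (k-1 = 1), SSW = 4 (n-k = 4) -> 54/1."""
    values = [1, 2, 3, 7, 8, 9]
    labels = ["a"] * 3 + ["b"] * 3
    assert daf(values, labels) == pytest.approx(54.0)


def test_daf_no_separation_and_infinite_flag():
    assert daf([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3) == 0.0
    assert daf([1, 1, 5, 5], ["a", "a", "b", "b"]) == math.inf
    assert daf([1, 1, 1, 1], ["a", "a", "b", "b"]) == 0.0
    with pytest.raises(ValueError):
        daf([1, 2, 3], ["a", "a", "b"])  # degenerate group


def test_daf_equals_anova_f_on_random_instances(rng):
    """Cross-check against scipy's independently coded one-way ANOVA."""
    for _ in range(25):
        sizes = rng.integers(2, 8, size=rng.integers(2, 4))
        groups = [rng.normal(rng.normal(0, 2), 1, size=s) for s in sizes]
        values = np.concatenate(groups)
        labels = np.concatenate([[f"g{i}"] * s for i, s in enumerate(sizes)])
        f_ref = stats.f_oneway(*groups).statistic
        assert daf(values, labels) == pytest.approx(float(f_ref), rel=1e-10)


@settings(deadline=None, max_examples=30)
@given(shift=st.floats(-1e3, 1e3, allow_nan=False))
def test_daf_location_invariance(shift):
    values = np.array([1.0, 2.5, 3.0, 7.0, 8.5, 9.0])
    labels = ["a"] * 3 + ["b"] * 3
    assert daf(values + shift, labels) == pytest.approx(daf(values, labels),
                                                        rel=1e-9)


def test_daf_vector_trace_form(rng):
    X = rng.normal(size=(20, 4))
    X[10:] += 2.0
    labels = ["a"] * 10 + ["b"] * 10
    per_column = [daf(X[:, j], labels) for j in range(4)]
    vec = daf(X, labels)
    assert min(per_column) < vec < max(per_column)  # trace ratio mixes columns


def test_rank_conditions_ordering_and_ties(rng):
    labels = ["a"] * 10 + ["b"] * 10
    base = np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 10)])
    wide = np.concatenate([base[:10], base[10:] + 2.0])  # double the gap
    ranked = rank_conditions({"set 1": base, "set 2": wide}, labels)
    assert [r.condition_id for r in ranked] == ["set 2", "set 1"]
    assert ranked[0].daf > ranked[1].daf

    tied = rank_conditions({"b": base, "a": base, "c": base}, labels)
    assert [r.condition_id for r in tied] == ["a", "b", "c"]

    single = rank_conditions({"only": base}, labels)
    assert len(single) == 1 and single[0].condition_id == "only"


# ---------------------------------------------------------------- t-test

def test_ttest_identical_groups():
    res = two_sample_ttest(5.0, 1.0, 10, 5.0, 1.0, 10)
    assert res.t == 0.0 and res.p == pytest.approx(1.0)


def test_ttest_printed_group_summaries():
    """The reported norm summaries separate at P < 0.001."""
    res = two_sample_ttest(358.31, 27.98, 45, 328.47, 31.60, 45)
    assert res.p < 0.001
    assert res.df == 88
    assert res.t > 0


def test_ttest_degenerate_zero_variance():
    res = two_sample_ttest(3.0, 0.0, 5, 3.0, 0.0, 5)
    assert res.t == 0.0 and res.p == 1.0
    res = two_sample_ttest(4.0, 0.0, 5, 3.0, 0.0, 5)
    assert math.isinf(res.t) and res.p == 0.0


def test_ttest_p_against_quadrature_oracle(rng):
    """p-value equals the numerically integrated t density tail mass."""
    x = rng.normal(0.0, 1.0, 12)
    y = rng.normal(0.8, 1.3, 15)
    res = two_sample_ttest_samples(x, y)
    df = res.df

    def t_pdf(u):
        return math.exp(math.lgamma((df + 1) / 2) - math.lgamma(df / 2)) \
            / math.sqrt(df * math.pi) * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(t_pdf, abs(res.t), np.inf)
    assert res.p == pytest.approx(2 * tail, rel=1e-8)

    ref = stats.ttest_ind(x, y, equal_var=True)
    assert res.t == pytest.approx(float(ref.statistic), rel=1e-12)
    welch = two_sample_ttest_samples(x, y, variant="welch")
    ref_w = stats.ttest_ind(x, y, equal_var=False)
    assert welch.p == pytest.approx(float(ref_w.pvalue), rel=1e-12)


# ---------------------------------------------------------------- Pearson

def test_pearson_reference_cases():
    x = np.array([1.0, 2.0, 3.0])
    assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
    assert pearson(x, -x).r == pytest.approx(-1.0)
    # hand covariance: cov = 0.5, sds = 1 -> r = 0.5
    assert pearson(x, np.array([1.0, 3.0, 2.0])).r == pytest.approx(0.5)
    with pytest.raises(ValueError):
        pearson(x, np.array([2.0, 2.0, 2.0]))
    with pytest.raises(ValueError):
        pearson(x[:2], np.array([1.0, 2.0]))


@settings(deadline=None, max_examples=30)
@given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
def test_pearson_affine_invariance(a, b):
    x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
    y = np.array([2.0, 1.0, 5.0, 7.0, 11.0])
    base = pearson(x, y).r
    assert pearson(a * x + b, y).r == pytest.approx(base, rel=1e-9)
    assert pearson(-x, y).r == pytest.approx(-base, rel=1e-9)


# ---------------------------------------------------------------- RSD, bins

def test_rsd_cases():
    assert rsd_percent([5.0, 5.0, 5.0]) == 0.0
    assert rsd_percent([9.0, 10.0, 11.0]) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        rsd_percent([4.0])
    with pytest.raises(ValueError):
        rsd_percent([-1.0, 1.0])


def test_fbg_bin_midpoints():
    mids = fbg_bin_midpoints([95, 100, 125.9, 126, 199, 200, 300],
                             (0, 100, 126, 200), 250.0)
    assert list(mids) == [50.0, 113.0, 113.0, 163.0, 163.0, 250.0, 250.0]


# ---------------------------------------------------------------- threshold

def test_threshold_rule_and_tie_contract():
    preds = threshold_classify([343.40, 343.38], 343.39)
    assert list(preds) == ["diabetic", "nondiabetic"]
    preds = threshold_classify([343.39, 343.39], 343.39)
    assert list(preds) == ["nondiabetic", "nondiabetic"]  # ties go negative


def test_threshold_accuracy_matches_normal_model(rng):
    """Large-n accuracy of the grand-mean rule equals the averaged normal
    tail probabilities, checked against a 10^6-draw Monte-Carlo oracle."""
    n = 500_000
    thr = 343.39
    d = rng.normal(358.31, 27.98, n)
    nd = rng.normal(328.47, 31.60, n)
    mc = 0.5 * ((d > thr).mean() + (nd <= thr).mean())
    closed = 0.5 * (stats.norm.sf((thr - 358.31) / 27.98)
                    + stats.norm.cdf((thr - 328.47) / 31.60))
    norms = np.concatenate([d, nd])
    labels = np.array(["diabetic"] * n + ["nondiabetic"] * n)
    rep = confusion_metrics(confusion_counts(labels,
                                             threshold_classify(norms, thr)))
    assert mc == pytest.approx(closed, abs=0.002)
    assert rep.accuracy / 100 == pytest.approx(closed, abs=0.002)


def test_norm_threshold_classifier_estimator(responses, labels):
    from sklearn.base import clone
    clf = NormThresholdClassifier()
    clone(clf).fit(responses.to_numpy(), labels)
    fitted = clf.fit(responses.to_numpy(), labels)
    norms = np.linalg.norm(responses.to_numpy(), axis=1)
    assert fitted.threshold_ == pytest.approx(norms.mean())
    preds = fitted.predict(responses.to_numpy())
    assert set(preds) <= {"diabetic", "nondiabetic"}
    fixed = NormThresholdClassifier(threshold=343.39).fit(responses.to_numpy())
    assert fixed.threshold_ == 343.39


# ---------------------------------------------------------------- summary

def test_total_response_summary_grand_mean_identity(responses, labels):
    s = total_response_summary(responses.to_numpy(), labels)
    assert s.grand_mean == pytest.approx((s.mean_d + s.mean_nd) / 2, rel=1e-12)
    assert s.mean_difference == pytest.approx(s.mean_d - s.mean_nd)


# ---------------------------------------------------------------- confusion

def test_confusion_metrics_printed_outcome():
    """41/45 diabetic and 39/45 non-diabetic correct -> accuracy 88.9%,
    error 11.1%, diabetic sensitivity 91.1% after one-decimal rounding."""
    rep = confusion_metrics(np.array([[41, 4], [6, 39]]))
    rounded = rep.rounded()
    assert rounded["accuracy"] == 88.9
    assert rounded["error_rate"] == 11.1
    assert rounded["sensitivity"]["diabetic"] == 91.1
    # 39/45 rounds to 86.7 under half-away rounding
    assert rounded["sensitivity"]["nondiabetic"] == 86.7


def test_confusion_metrics_degenerate_cases():
    perfect = confusion_metrics(np.array([[10, 0], [0, 10]]))
    assert perfect.accuracy == 100.0 and perfect.error_rate == 0.0
    wrong = confusion_metrics(np.array([[0, 10], [10, 0]]))
    assert wrong.accuracy == 0.0
    assert wrong.sensitivity["diabetic"] == 0.0
    empty_class = confusion_metrics(np.array([[0, 0], [3, 7]]))
    assert empty_class.sensitivity["diabetic"] is None
    with pytest.raises(ValueError):
        confusion_metrics(np.array([[0, 0], [0, 0]]))


@settings(deadline=None, max_examples=50)
@given(st.lists(st.integers(0, 40), min_size=4, max_size=4))
def test_two_class_identity(counts):
    """sensitivity(A) = specificity(B) for every 2x2 confusion table."""
    c = np.array(counts).reshape(2, 2)
    if c.sum() == 0:
        return
    rep = confusion_metrics(c)
    assert rep.specificity["diabetic"] == rep.sensitivity["nondiabetic"]
    assert rep.specificity["nondiabetic"] == rep.sensitivity["diabetic"]
    assert rep.accuracy + rep.error_rate == pytest.approx(100.0)
    assert rep.n == c.sum()
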