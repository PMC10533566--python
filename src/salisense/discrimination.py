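"""PCA-LDA discrimination of the two participant groups.

The 36-feature colour-difference matrix is mean-centred and decomposed into
principal components; the leading components (enough to cover a cumulative
explained-variance target, 95% by default) feed a two-class Fisher linear
discriminant.  Both stages are implemented from first principles on top of
numpy's symmetric eigensolver so every numerical convention (component
ordering, sign fixing, ridge regularisation, threshold placement) is
explicit and testable.

:class:`PCALDAClassifier` packages the chain as a scikit-learn estimator;
``pca_fit`` / ``lda_fit`` / ``crossvalidate`` are the function-level
interface.  Cross-validation refits the *whole* pipeline (PCA included)
inside every training fold, so no information from held-out samples leaks
into the decomposition; resubstitution mode reproduces the optimistic
fit-once protocol for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .chemometrics import (ClassificationReport, PearsonResult,
                           confusion_counts, confusion_metrics, pearson)
from .panel import DIABETIC, NONDIABETIC


# --------------------------------------------------------------------------
# PCA

@dataclass(frozen=True)
class PCAModel:
    """Mean-centred principal-component decomposition.

    ``components`` rows are orthonormal loading vectors ordered by
    decreasing explained variance; the sign of each is fixed so its
    largest-magnitude element is positive (reproducible score plots).
    """

    mean: np.ndarray
    components: np.ndarray          # (k, p)
    explained_variance: np.ndarray  # (k,)
    explained_variance_ratio: np.ndarray
    total_variance: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean) @ self.components.T

    def inverse_transform(self, scores) -> np.ndarray:
        return np.asarray(scores, dtype=float) @ self.components + self.mean


def pca_fit(X, n_components: Optional[int] = None,
            variance_target: Optional[float] = None) -> PCAModel:
    """Fit a PCA model via eigendecomposition of the sample covariance.

    Exactly one retention rule applies: an explicit component count, a
    cumulative explained-variance target, or (neither given) all components.
    A constant matrix yields zero explained variance everywhere, flagged by
    ``total_variance == 0``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    n, p = X.shape
    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False, ddof=1).reshape(p, p)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    total = float(evals.sum())
    ratio = evals / total if total > 0 else np.zeros_like(evals)

    if n_components is not None:
        k = min(int(n_components), p)
    elif variance_target is not None:
        k = int(np.searchsorted(np.cumsum(ratio), variance_target) + 1)
        k = min(k, p)
    else:
        k = p

    components = evecs[:, :k].T.copy()
    for i, comp in enumerate(components):  # sign convention
        j = int(np.argmax(np.abs(comp)))
        if comp[j] < 0:
            components[i] = -comp
    return PCAModel(mean=mean, components=components,
                    explained_variance=evals[:k],
                    explained_variance_ratio=ratio[:k],
                    total_variance=total)


# --------------------------------------------------------------------------
# LDA

@dataclass(frozen=True)
class LDAModel:
    """Two-class Fisher discriminant in PC-score space.

    ``direction`` is the unit vector along pooled-within-scatter^-1 times
    the class-mean difference, oriented so diabetic projects high;
    ``threshold`` is the equal-covariance Gaussian decision point, which
    reduces to the midpoint of the projected class means under equal priors.
    """

    direction: np.ndarray
    threshold: float
    class_means: Dict[str, float]
    priors: Dict[str, float]
    classes: Tuple[str, str] = (DIABETIC, NONDIABETIC)

    def project(self, scores) -> np.ndarray:
        return np.asarray(scores, dtype=float) @ self.direction

    def predict(self, scores) -> np.ndarray:
        return np.where(self.project(scores) > self.threshold,
                        DIABETIC, NONDIABETIC)


def lda_fit(scores, labels, ridge: float = 1e-8,
            priors: Optional[Dict[str, float]] = None) -> LDAModel:
    """Fit the Fisher discriminant on PC scores with two classes.

    A ridge term ``ridge * mean(diag(Sw)) * I`` stabilises the pooled
    within-class scatter when it is (near) singular.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.ndim != 2:
        raise ValueError("scores must be 2-D (n_samples, n_components)")
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    if present != {DIABETIC, NONDIABETIC}:
        raise ValueError(f"need exactly the two classes {DIABETIC!r}/{NONDIABETIC!r}, "
                         f"got {sorted(present)}")
    n, k = S.shape
    blocks = {c: S[labels == c] for c in (DIABETIC, NONDIABETIC)}
    for c, b in blocks.items():
        if b.shape[0] < 2:
            raise ValueError(f"class {c!r} needs at least 2 samples")

    mu = {c: b.mean(axis=0) for c, b in blocks.items()}
    sw = sum((b - mu[c]).T @ (b - mu[c]) for c, b in blocks.items()) / (n - 2)
    scale = np.trace(sw) / k if np.trace(sw) > 0 else 1.0
    sw = sw + ridge * scale * np.eye(k)
    w = np.linalg.solve(sw, mu[DIABETIC] - mu[NONDIABETIC])
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate discriminant: identical class means")
    w = w / norm
    m = {c: float(mu[c] @ w) for c in blocks}
    if m[DIABETIC] < m[NONDIABETIC]:  # orient diabetic-high
        w = -w
        m = {c: -v for c, v in m.items()}

    if priors is None:
        priors = {c: b.shape[0] / n for c, b in blocks.items()}
    s2 = float(w @ sw @ w)
    threshold = (m[DIABETIC] + m[NONDIABETIC]) / 2.0
    gap = m[DIABETIC] - m[NONDIABETIC]
    if gap > 0 and s2 > 0:
        threshold -= s2 * np.log(priors[DIABETIC] / priors[NONDIABETIC]) / gap
    return LDAModel(direction=w, threshold=float(threshold),
                    class_means=m, priors=dict(priors))


# --------------------------------------------------------------------------
# estimator

class PCALDAClassifier(BaseEstimator, ClassifierMixin):
    """PCA followed by a two-class Fisher discriminant.

    Parameters
    ----------
    n_components : int, optional
        Fixed number of retained components; overrides ``variance_target``.
    variance_target : float, default 0.95
        Retain the smallest leading set of components reaching this
        cumulative explained-variance fraction.
    ridge : float, default 1e-8
        Relative ridge added to the pooled within-class scatter.
    priors : dict, optional
        Class priors; empirical frequencies when omitted.

    Attributes
    ----------
    pca_ : fitted :class:`PCAModel`
    lda_ : fitted :class:`LDAModel`
    classes_ : array of the two class labels
    n_components_ : retained component count
    """

    def __init__(self, n_components: Optional[int] = None,
                 variance_target: float = 0.95, ridge: float = 1e-8,
                 priors: Optional[Dict[str, float]] = None):
        self.n_components = n_components
        self.variance_target = variance_target
        self.ridge = ridge
        self.priors = priors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.n_components is not None:
            self.pca_ = pca_fit(X, n_components=self.n_components)
        else:
            self.pca_ = pca_fit(X, variance_target=self.variance_target)
        self.lda_ = lda_fit(self.pca_.transform(X), y,
                            ridge=self.ridge, priors=self.priors)
        self.classes_ = np.array(sorted(np.unique(y)))
        self.n_components_ = self.pca_.n_components
        return self

    def transform(self, X) -> np.ndarray:
        return self.pca_.transform(X)

    def decision_function(self, X) -> np.ndarray:
        return self.lda_.project(self.transform(X)) - self.lda_.threshold

    def predict(self, X) -> np.ndarray:
        return self.lda_.predict(self.transform(X))


# --------------------------------------------------------------------------
# cross-validation

def _fold_indices(y: np.ndarray, scheme: str, k: int, seed: int):
    n = y.shape[0]
    if scheme == "resubstitution":
        idx = np.arange(n)
        yield idx, idx
    elif scheme == "loo":
        for i in range(n):
            train = np.delete(np.arange(n), i)
            yield train, np.array([i])
    elif scheme == "kfold":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        yield from splitter.split(np.zeros(n), y)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")


def crossvalidate(X, labels, scheme: str = "loo", k: int = 5, seed: int = 0,
                  n_components: Optional[int] = None,
                  variance_target: float = 0.95,
                  ridge: float = 1e-8) -> ClassificationReport:
    """Pooled-confusion classification report for the PCA-LDA pipeline.

    ``loo`` (deterministic, the default for a 90-sample panel study),
    stratified ``kfold`` (deterministic given ``seed``), or
    ``resubstitution``.  Every training fold must contain both classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    y_pred = np.empty(y.shape, dtype=y.dtype)
    for train, test in _fold_indices(y, scheme, k, seed):
        if len(set(y[train])) < 2:
            raise ValueError("a training fold lost one of the classes; "
                             "use fewer folds or more samples")
        clf = PCALDAClassifier(n_components=n_components,
                               variance_target=variance_target, ridge=ridge)
        clf.fit(X[train], y[train])
        y_pred[test] = clf.predict(X[test])
    return confusion_metrics(confusion_counts(y, y_pred))


# --------------------------------------------------------------------------
# score export

def export_scores(X, labels, pca_model: PCAModel, fbg=None, ids=None,
                  csv_path=None, plot_path=None
                  ) -> Tuple[pd.DataFrame, Optional[PearsonResult]]:
    """Per-sample PC1/PC2 score table, optional CSV/scatter-plot export.

    Returns the table and, when FBG values are supplied, the Pearson
    correlation between the PC1 score and FBG (sign depends on the component
    orientation convention).
    """
    X = np.asarray(X, dtype=float)
    scores = pca_model.transform(X)
    pc2 = scores[:, 1] if scores.shape[1] > 1 else np.zeros(scores.shape[0])
    table = pd.DataFrame({
        "id": np.asarray(ids) if ids is not None
        else np.array([f"sample{i + 1:03d}" for i in range(X.shape[0])]),
        "group": np.asarray(labels),
        "PC1": scores[:, 0],
        "PC2": pc2,
    })
    corr = None
    if fbg is not None:
        table["fbg"] = np.asarray(fbg, dtype=float)
        corr = pearson(table["PC1"], table["fbg"])
    if csv_path is not None:
        table.to_csv(csv_path, index=False, float_format="%.6f")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        for grp, marker, color in ((DIABETIC, "o", "tab:red"),
                                   (NONDIABETIC, "s", "tab:blue")):
            sel = table["group"] == grp
            ax.scatter(table.loc[sel, "PC1"], table.loc[sel, "PC2"],
                       marker=marker, color=color, label=grp, alpha=0.8)
        var = pca_model.explained_variance_ratio
        ax.set_xlabel(f"PC1 ({100 * var[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * var[1]:.1f}%)" if var.size > 1 else "PC2")
        ax.legend()
        ax.set_title("PCA-LDA score plot")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return table, corr
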