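"""End-to-end statistics report for one response matrix + cohort.

Aggregates the full statistical read-out of one cohort: the total-response
(norm) summary with the grand-mean threshold rule, PCA-LDA discrimination
under the chosen validation scheme, and the correlation analyses (MR+TBOH
vs binned FBG, TMA-AgNPs vs FBG, age vs total response per group).  Every
numeric in the report is finite or explicitly null with a reason string.
"""

from __future__ import annotations

import json
import math
from typing import Optional

import numpy as np
import pandas as pd

from .chemometrics import (confusion_counts, confusion_metrics, daf,
                           fbg_bin_midpoints, pearson, rank_conditions,
                           threshold_classify, total_response_summary)
from .config import AnalysisConfig
from .discrimination import crossvalidate, export_scores, pca_fit
from .panel import DIABETIC, NONDIABETIC


def _jsonable(obj):
    """Recursively convert to JSON-safe values; non-finite floats become
    null-with-reason markers."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isnan(f):
            return {"value": None, "reason": "not a number"}
        if math.isinf(f):
            return {"value": None, "reason": "infinite"}
        return f
    return obj


def _receptor_summary(matrix: pd.DataFrame, index: int) -> np.ndarray:
    """Per-sample magnitude of one receptor: norm of its 3 channels."""
    cols = [f"S{index}_{c}" for c in "RGB"]
    return np.linalg.norm(matrix[cols].to_numpy(dtype=float), axis=1)


def _safe_pearson(x, y) -> dict:
    try:
        res = pearson(x, y)
        return {"r": res.r, "p": res.p, "n": res.n}
    except ValueError as exc:
        return {"r": None, "p": None, "n": int(np.asarray(x).size),
                "reason": str(exc)}


def analyze(matrix: pd.DataFrame, cohort: pd.DataFrame,
            config: Optional[AnalysisConfig] = None,
            conditions: Optional[dict] = None,
            scores_csv=None, plot_path=None) -> dict:
    """Full statistics report as a JSON-serialisable dict.

    ``matrix`` rows and ``cohort`` rows are joined on participant id; a
    mismatch raises with the offending ids listed.  ``conditions`` may map
    a condition id to per-sample responses measured under that condition
    (e.g. a fabrication sweep); by default the acquired data form the
    single scored condition.  With only one group
    present, discrimination and the group-comparison statistics are skipped
    with an explicit notice while per-sample norms are still reported.
    """
    config = config or AnalysisConfig()
    cohort = cohort.set_index("id") if "id" in cohort.columns else cohort
    matrix_ids = list(matrix.index.astype(str))
    cohort_ids = list(cohort.index.astype(str))
    only_m = sorted(set(matrix_ids) - set(cohort_ids))
    only_c = sorted(set(cohort_ids) - set(matrix_ids))
    if only_m or only_c:
        raise ValueError("id mismatch between response matrix and cohort: "
                         f"matrix-only={only_m[:5]}, cohort-only={only_c[:5]}")
    cohort = cohort.loc[matrix.index]
    labels = cohort["group"].to_numpy()
    fbg = cohort["fbg"].to_numpy(dtype=float)
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    groups_present = sorted(set(labels))
    two_groups = len(groups_present) == 2

    report: dict = {"n_samples": n, "groups": groups_present}

    norms = np.linalg.norm(X, axis=1)
    report["per_sample"] = {
        "ids": matrix_ids,
        "norms": norms,
    }

    if two_groups:
        summary = total_response_summary(X, labels, variant=config.ttest_variant)
        threshold = config.threshold if config.threshold is not None \
            else summary.grand_mean
        predicted = threshold_classify(norms, threshold)
        thr_report = confusion_metrics(confusion_counts(labels, predicted))
        report["total_response"] = {
            "mean_all": summary.grand_mean,
            "mean_diabetic": summary.mean_d, "sd_diabetic": summary.sd_d,
            "mean_nondiabetic": summary.mean_nd, "sd_nondiabetic": summary.sd_nd,
            "mean_difference": summary.mean_difference,
            "t": summary.ttest.t, "p": summary.ttest.p,
            "df": summary.ttest.df, "variant": summary.ttest.variant,
        }
        report["threshold_rule"] = {
            "threshold": threshold,
            "source": "override" if config.threshold is not None else "grand_mean",
            "confusion": thr_report.confusion,
            **thr_report.rounded(),
        }
        cv = crossvalidate(X, labels, scheme=config.cv_scheme, k=config.kfold_k,
                           seed=0, n_components=config.n_components,
                           variance_target=config.variance_target,
                           ridge=config.ridge)
        pca = pca_fit(X, n_components=config.n_components) \
            if config.n_components is not None \
            else pca_fit(X, variance_target=config.variance_target)
        table, pc1_corr = export_scores(X, labels, pca, fbg=fbg, ids=matrix_ids,
                                        csv_path=scores_csv, plot_path=plot_path)
        full = pca_fit(X)
        report["discrimination"] = {
            "scheme": config.cv_scheme,
            "n_components": pca.n_components,
            "explained_variance_pc1_pc2_percent":
                float(100 * full.explained_variance_ratio[:2].sum()),
            "confusion": cv.confusion,
            **cv.rounded(),
            "pc1_fbg": {"r": pc1_corr.r, "p": pc1_corr.p} if pc1_corr else None,
        }
    else:
        report["total_response"] = {
            "mean_all": float(norms.mean()),
            "notice": "single group present; group comparison skipped",
        }
        report["threshold_rule"] = None
        report["discrimination"] = {
            "notice": "discrimination skipped: need both groups",
        }

    if two_groups:
        if conditions is None:
            conditions = {"acquired": norms}
        ranked = rank_conditions(conditions, labels)
        report["daf"] = {
            "best_condition": ranked[0].condition_id,
            "table": [{"condition_id": r.condition_id, "daf": r.daf,
                       "n_per_group": list(r.n_per_group)} for r in ranked],
            "daf_matrix": daf(X, labels),
        }
    else:
        report["daf"] = {"notice": "DAF skipped: need at least two groups"}

    correlations = {
        "mr_tboh_vs_fbg_binned": _safe_pearson(
            fbg_bin_midpoints(fbg, config.fbg_bin_edges, config.fbg_top_bin_value),
            _receptor_summary(matrix, 5)),
        "tma_agnp_vs_fbg": _safe_pearson(fbg, _receptor_summary(matrix, 10)),
    }
    for grp in (DIABETIC, NONDIABETIC):
        sel = labels == grp
        correlations[f"age_vs_norm_{grp}"] = (
            _safe_pearson(cohort.loc[sel, "age"], norms[sel]) if sel.sum() >= 3
            else {"r": None, "p": None, "n": int(sel.sum()),
                  "reason": "fewer than 3 samples"})
    report["correlations"] = correlations
    return _jsonable(report)


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
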