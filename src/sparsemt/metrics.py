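"""Per-assay performance measures, median aggregation and degradation curves.

All scores are computed assay by assay on held-out compounds, then summarized
as the median across assays. Progression curves track that median over the
removal-fraction grid, both in absolute terms and relative to the
complete-data model (metric at fraction f divided by the metric at f = 0, so
every curve starts at exactly 1). The knee of a curve — the first grid
fraction at which performance has degraded by more than a chosen relative
amount — is located without interpolation.

Conventions for degenerate slices: bounded classification scores with a zero
denominator are 0 (scikit-learn's convention, shared by MCC); correlation-based
regression scores with a zero-variance truth are undefined and excluded from
medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)

REGRESSION_METRICS = ("rmsd", "mae", "r2", "rho2")
CLASSIFICATION_METRICS = ("precision", "recall", "f1", "mcc")

#: degradation direction: "up" = larger is worse (error metrics)
METRIC_DIRECTION = {
    "rmsd": "up", "mae": "up",
    "r2": "down", "rho2": "down",
    "precision": "down", "recall": "down", "f1": "down", "mcc": "down",
}


def regression_scores_single(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """RMSD, MAE, R^2 and squared Pearson correlation for one assay.

    rho^2 and R^2 need variance in the truth; with a constant truth (or a
    constant prediction, for rho^2) they are recorded as NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ok = ~(np.isnan(y_true) | np.isnan(y_pred))
    y_true, y_pred = y_true[ok], y_pred[ok]
    if y_true.size == 0:
        return {m: np.nan for m in REGRESSION_METRICS}
    resid = y_true - y_pred
    out = {
        "rmsd": float(np.sqrt(np.mean(resid ** 2))),
        "mae": float(np.mean(np.abs(resid))),
    }
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if y_true.size < 2 or ss_tot == 0.0:
        out["r2"] = np.nan
        out["rho2"] = np.nan
        return out
    out["r2"] = 1.0 - float((resid ** 2).sum()) / ss_tot
    if np.std(y_pred) == 0.0:
        out["rho2"] = np.nan
    else:
        out["rho2"] = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    return out


def classification_scores_single(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Precision, recall, F1 and MCC from the confusion counts of one assay.

    Any zero denominator yields 0 for that score.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ok = ~(np.isnan(y_true) | np.isnan(y_pred))
    y_true, y_pred = y_true[ok], y_pred[ok]
    for arr, name in ((y_true, "labels_true"), (y_pred, "labels_pred")):
        if arr.size and not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    if y_true.size == 0:
        return {m: np.nan for m in CLASSIFICATION_METRICS}
    yt = y_true.astype(int)
    yp = y_pred.astype(int)
    with warnings.catch_warnings():
        # single-label slices are legitimate here; the zero-denominator
        # convention (score = 0) covers them
        warnings.simplefilter("ignore", UserWarning)
        return {
            "precision": float(precision_score(yt, yp, zero_division=0)),
            "recall": float(recall_score(yt, yp, zero_division=0)),
            "f1": float(f1_score(yt, yp, zero_division=0)),
            "mcc": float(matthews_corrcoef(yt, yp)),
        }


def _per_assay(test_values: np.ndarray, test_observed: np.ndarray,
               predictions: np.ndarray, assay_ids: list[str],
               scorer) -> pd.DataFrame:
    rows = []
    for j, aid in enumerate(assay_ids):
        sel = test_observed[:, j]
        scores = scorer(test_values[sel, j], predictions[sel, j])
        rows.append({"assay_id": aid, **scores})
    return pd.DataFrame(rows).set_index("assay_id")


def regression_scores(test, predictions: np.ndarray) -> pd.DataFrame:
    """Per-assay regression scores of a prediction grid against a test ActivityMatrix."""
    return _per_assay(np.nan_to_num(test.values), test.observed, predictions,
                      test.assay_ids, regression_scores_single)


def classification_scores(test, predictions: np.ndarray) -> pd.DataFrame:
    return _per_assay(np.nan_to_num(test.values), test.observed, predictions,
                      test.assay_ids, classification_scores_single)


def score_matrix(test, predictions: np.ndarray) -> pd.DataFrame:
    """Dispatch on the test matrix task type."""
    if predictions.shape != test.shape:
        raise ValueError(f"prediction shape {predictions.shape} != test shape {test.shape}")
    if test.task_type == "classification":
        return classification_scores(test, predictions)
    return regression_scores(test, predictions)


@dataclass
class ProgressionCurve:
    """Median-across-assays metric along the removal-fraction grid."""

    fractions: np.ndarray
    median: np.ndarray
    relative: np.ndarray
    metric: str
    method: str = ""
    removal_model: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fraction": self.fractions,
            "median": self.median,
            "relative": self.relative,
            "metric": self.metric,
            "method": self.method,
            "removal_model": self.removal_model,
        })


def aggregate(per_fraction_scores: dict[float, pd.DataFrame], metric: str,
              method: str = "", removal_model: str = "") -> ProgressionCurve:
    """Median metric across assays per fraction, scaled relative to fraction 0.

    Assays with undefined (NaN) scores are excluded from each fraction's
    median independently. The complete-data run at fraction 0 must be present;
    its relative value is exactly 1.
    """
    if 0.0 not in per_fraction_scores:
        raise ValueError("complete-data run (fraction 0) is required for relative scaling")
    fractions = np.array(sorted(per_fraction_scores))
    medians = np.array([
        float(np.nanmedian(per_fraction_scores[f][metric].to_numpy()))
        if np.isfinite(per_fraction_scores[f][metric].to_numpy()).any() else np.nan
        for f in fractions
    ])
    base = medians[fractions == 0.0][0]
    if not np.isfinite(base) or base == 0.0:
        relative = np.full_like(medians, np.nan)
    else:
        relative = medians / base
        relative[fractions == 0.0] = 1.0
    return ProgressionCurve(fractions, medians, relative, metric, method, removal_model)


def threshold_crossing(curve: ProgressionCurve, rel_change: float = 0.10) -> float | None:
    """First grid fraction whose relative metric is worse than the threshold.

    Error metrics (RMSD, MAE) are worse above 1 + rel_change; quality metrics
    below 1 - rel_change. No interpolation between grid points; None if the
    curve never crosses.
    """
    direction = METRIC_DIRECTION[curve.metric]
    for f, rel in zip(curve.fractions, curve.relative):
        if not np.isfinite(rel):
            continue
        if direction == "up" and rel > 1.0 + rel_change:
            return float(f)
        if direction == "down" and rel < 1.0 - rel_change:
            return float(f)
    return None
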