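"""Multi-output random-forest baseline requiring complete training matrices.

Tree ensembles here cannot consume sparse target matrices: a fit on any
matrix with missing cells raises and points the caller at the
compound-removal model, the only sparsification under which the training
matrix stays complete. The small number of pre-existing gaps in an otherwise
complete panel is handled by :func:`impute_assay_mean` (each missing cell
replaced by its assay's observed mean) before fitting.

The trees themselves are scikit-learn's multi-output random forests;
regression combines trees by mean, classification by majority vote with
ties resolved to active.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .matrix import ActivityMatrix, FingerprintSet


def impute_assay_mean(matrix: ActivityMatrix) -> ActivityMatrix:
    """Replace each missing cell by its assay's observed mean; idempotent.

    The mask becomes all-true; observed values are untouched. A fully
    missing assay has no mean to impute and raises.
    """
    if matrix.observed.all():
        return matrix.copy()
    empty = np.where(~matrix.observed.any(axis=0))[0]
    if empty.size:
        names = [matrix.assay_ids[j] for j in empty[:10]]
        raise ValueError(f"cannot impute assay(s) with no observed values: {names}")
    values = matrix.values.copy()
    for j in range(matrix.n_assays):
        col_obs = matrix.observed[:, j]
        if not col_obs.all():
            col_mean = matrix.values[col_obs, j].mean()
            values[~col_obs, j] = col_mean
    if matrix.task_type == "classification":
        values = np.round(values)  # imputed label = majority-leaning mean, rounded
    return ActivityMatrix(values, np.ones(matrix.shape, dtype=bool),
                          matrix.compound_ids, matrix.assay_ids, matrix.task_type)


_SPARSE_MSG = (
    "random-forest baseline requires a complete training matrix; it can only be "
    "used with the compound removal model (impute pre-existing gaps with "
    "impute_assay_mean first)"
)


class _ForestBase(BaseEstimator):
    def __init__(self, n_trees: int = 100, max_features="sqrt", bootstrap: bool = True,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.random_state = random_state

    def _check(self, X: np.ndarray, Y: np.ndarray) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if np.isnan(Y).any():
            raise ValueError(_SPARSE_MSG)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have matching row counts")


class ActivityForestRegressor(RegressorMixin, _ForestBase):
    """Multi-output regression forest over fingerprint bits (mean of trees)."""

    def fit(self, X: np.ndarray, Y: np.ndarray):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        self._check(X, Y)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees, max_features=self.max_features,
            bootstrap=self.bootstrap, random_state=self.random_state, n_jobs=1,
        ).fit(X, Y.ravel() if Y.shape[1] == 1 else Y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        P = self.forest_.predict(np.asarray(X, dtype=float))
        return P.reshape(len(X), -1)


class ActivityForestClassifier(ClassifierMixin, _ForestBase):
    """Multi-output classification forest; majority vote, ties -> active."""

    def fit(self, X: np.ndarray, Y: np.ndarray):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        self._check(X, Y)
        if not np.isin(Y, (0.0, 1.0)).all():
            raise ValueError("classification labels must be in {0, 1}")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, max_features=self.max_features,
            bootstrap=self.bootstrap, random_state=self.random_state, n_jobs=1,
        ).fit(X, Y.ravel() if Y.shape[1] == 1 else Y)
        self._single_class_ = [np.unique(Y[:, j]) for j in range(Y.shape[1])]
        self.n_assays_ = Y.shape[1]
        return self

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        """P(active) per assay; constant-class assays give 0 or 1 exactly."""
        X = np.asarray(X, dtype=float)
        probas = self.forest_.predict_proba(X)
        if self.n_assays_ == 1:
            probas = [probas]
        out = np.empty((X.shape[0], self.n_assays_))
        for j, pj in enumerate(probas):
            cls = self._single_class_[j]
            if len(cls) == 1:
                out[:, j] = float(cls[0])
            else:
                # column order of predict_proba follows sorted classes {0, 1}
                out[:, j] = pj[:, 1]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Vote fraction >= 0.5 -> active (tie resolves to active)."""
        return (self.predict_proba_matrix(X) >= 0.5).astype(float)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fit(train_complete: ActivityMatrix, fps: FingerprintSet, *, n_trees: int = 100,
        max_features="sqrt", bootstrap: bool = True, seed: int = 0):
    if not train_complete.observed.all():
        raise ValueError(_SPARSE_MSG)
    fps = fps.align_to(train_complete)
    cls = (ActivityForestClassifier if train_complete.task_type == "classification"
           else ActivityForestRegressor)
    est = cls(n_trees=n_trees, max_features=max_features, bootstrap=bootstrap,
              random_state=seed)
    est.fit(fps.bits.astype(float), train_complete.values)
    est.assay_ids_ = list(train_complete.assay_ids)
    return est


def predict(model, fps_new: FingerprintSet) -> np.ndarray:
    return model.predict(fps_new.bits.astype(float))
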