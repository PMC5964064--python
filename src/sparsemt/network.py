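"""Fully connected multitask network with a masked cost, in plain NumPy.

Architecture: 1024-bit fingerprint in, one output unit per assay (linear for
regression, sigmoid for classification), ReLU hidden layers with optional
(inverted) dropout. The cost is averaged over *observed* cells only, so
unobserved labels contribute exactly nothing to training — the property that
lets one network train on arbitrarily sparse activity matrices. Optimization
is Adagrad (learning rate 0.05 by default) over compound minibatches, each
minibatch carrying all of its compounds' observed labels.

Backpropagation, initialization and dropout are implemented directly so that
training is bit-reproducible from a seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from .matrix import ActivityMatrix, FingerprintSet
from .sparsify import audit_empty


def masked_loss(predictions: np.ndarray, values: np.ndarray, observed: np.ndarray,
                task_type: str = "regression") -> float:
    """Mean per-observed-cell loss; an empty mask contributes 0.

    Regression: squared error. Classification: binary cross-entropy on
    probabilities (predictions in (0, 1)).
    """
    predictions = np.asarray(predictions, dtype=float)
    values = np.asarray(values, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if predictions.shape != values.shape or values.shape != observed.shape:
        raise ValueError("predictions, values and mask must share a shape")
    n_obs = int(observed.sum())
    if n_obs == 0:
        return 0.0
    p = predictions[observed]
    y = values[observed]
    if task_type == "regression":
        return float(np.mean((p - y) ** 2))
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def masked_loss_matrix(predictions: np.ndarray, matrix: ActivityMatrix) -> float:
    return masked_loss(predictions, np.nan_to_num(matrix.values), matrix.observed,
                       matrix.task_type)


class _MaskedNet(BaseEstimator):
    """Shared training machinery; subclasses fix the task type."""

    _task: str = "regression"

    def __init__(self, hidden_sizes=(256,), dropout: float = 0.0,
                 train_steps: int = 2000, minibatch: int = 32,
                 learning_rate: float = 0.05, activation: str = "relu",
                 on_empty_assay: str = "error", random_state: int = 0):
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.train_steps = train_steps
        self.minibatch = minibatch
        self.learning_rate = learning_rate
        self.activation = activation
        self.on_empty_assay = on_empty_assay
        self.random_state = random_state

    # -- plumbing -------------------------------------------------------
    def _validate(self, X: np.ndarray, Y: np.ndarray) -> None:
        if len(self.hidden_sizes) < 1:
            raise ValueError("need at least one hidden layer")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.activation not in ("relu", "linear"):
            raise ValueError("activation must be 'relu' or 'linear'")
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2-D with matching row counts")

    def _init_weights(self, sizes: list[int], rng: np.random.Generator):
        W, b = [], []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            limit = np.sqrt(6.0 / fan_in)
            W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            b.append(np.zeros(fan_out))
        return W, b

    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def _act_grad(self, z: np.ndarray) -> np.ndarray:
        return (z > 0.0).astype(float) if self.activation == "relu" else np.ones_like(z)

    # -- training -------------------------------------------------------
    def fit(self, X: np.ndarray, Y: np.ndarray):
        """Fit on fingerprints X (n x bits) and activities Y (n x m, NaN = missing)."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        self._validate(X, Y)
        obs = ~np.isnan(Y)
        empty_cols = np.where(~obs.any(axis=0))[0]
        self._col_keep_ = np.ones(Y.shape[1], dtype=bool)
        if empty_cols.size:
            if self.on_empty_assay == "error":
                raise ValueError(
                    f"assay column(s) {empty_cols[:10].tolist()} have no observed labels"
                )
            self._col_keep_ = obs.any(axis=0)
            Y = Y[:, self._col_keep_]
            obs = obs[:, self._col_keep_]
        n, m = Y.shape
        Y0 = np.where(obs, Y, 0.0)

        if self._task == "regression":
            self._y_center_ = float(Y[obs].mean()) if obs.any() else 0.0
            self._y_scale_ = float(Y[obs].std()) or 1.0
        else:
            vals = Y[obs]
            if vals.size and not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("classification labels must be in {0, 1}")
            self._y_center_, self._y_scale_ = 0.0, 1.0
        Yn = np.where(obs, (Y0 - self._y_center_) / self._y_scale_, 0.0)

        rng = np.random.default_rng(self.random_state)
        sizes = [X.shape[1], *self.hidden_sizes, m]
        W, b = self._init_weights(sizes, rng)
        accW = [np.zeros_like(w) for w in W]
        accb = [np.zeros_like(v) for v in b]
        lr, eps = self.learning_rate, 1e-8

        order = np.empty(0, dtype=int)
        pos = 0
        losses = []
        for _ in range(self.train_steps):
            if pos + self.minibatch > order.size:
                order = rng.permutation(n)
                pos = 0
            idx = order[pos:pos + self.minibatch]
            pos += self.minibatch

            xb, yb, ob = X[idx], Yn[idx], obs[idx]
            # forward
            hs, zs, masks = [xb], [], []
            h = xb
            for li, (w, bias) in enumerate(zip(W, b)):
                z = h @ w + bias
                zs.append(z)
                last = li == len(W) - 1
                h = z if last else self._act(z)
                if not last and self.dropout > 0.0:
                    keep = rng.random(h.shape) >= self.dropout
                    h = h * keep / (1.0 - self.dropout)
                    masks.append(keep)
                elif not last:
                    masks.append(None)
                hs.append(h)
            out = hs[-1]

            n_obs = int(ob.sum())
            if self._task == "regression":
                diff = np.where(ob, out - yb, 0.0)
                loss = float((diff ** 2).sum() / n_obs) if n_obs else 0.0
                dout = (2.0 / n_obs) * diff if n_obs else np.zeros_like(diff)
            else:
                p = 1.0 / (1.0 + np.exp(-out))
                pc = np.clip(p, 1e-12, 1.0 - 1e-12)
                ll = -(yb * np.log(pc) + (1.0 - yb) * np.log(1.0 - pc))
                loss = float(np.where(ob, ll, 0.0).sum() / n_obs) if n_obs else 0.0
                dout = np.where(ob, p - yb, 0.0) / n_obs if n_obs else np.zeros_like(p)
            losses.append(loss)

            # backward
            grad = dout
            for li in range(len(W) - 1, -1, -1):
                gW = hs[li].T @ grad
                gb = grad.sum(axis=0)
                if li > 0:
                    grad = grad @ W[li].T
                    if self.dropout > 0.0 and masks[li - 1] is not None:
                        grad = grad * masks[li - 1] / (1.0 - self.dropout)
                    grad = grad * self._act_grad(zs[li - 1])
                accW[li] += gW ** 2
                accb[li] += gb ** 2
                W[li] -= lr * gW / (np.sqrt(accW[li]) + eps)
                b[li] -= lr * gb / (np.sqrt(accb[li]) + eps)

        self.weights_, self.biases_ = W, b
        self.loss_curve_ = np.asarray(losses)
        self.n_features_in_ = X.shape[1]
        return self

    # -- inference ------------------------------------------------------
    def _forward(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout disabled)."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"fingerprint width {X.shape[1]} != training width {self.n_features_in_}"
            )
        h = X
        for li, (w, bias) in enumerate(zip(self.weights_, self.biases_)):
            z = h @ w + bias
            h = z if li == len(self.weights_) - 1 else self._act(z)
        return h

    def _expand_cols(self, P: np.ndarray) -> np.ndarray:
        if self._col_keep_.all():
            return P
        out = np.full((P.shape[0], self._col_keep_.size), np.nan)
        out[:, self._col_keep_] = P
        return out


class MaskedNetRegressor(RegressorMixin, _MaskedNet):
    """Multitask regression network; linear outputs, masked MSE cost."""

    _task = "regression"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._expand_cols(self._forward(X) * self._y_scale_ + self._y_center_)


class MaskedNetClassifier(ClassifierMixin, _MaskedNet):
    """Multitask classification network; sigmoid outputs, masked cross-entropy."""

    _task = "classification"

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        return self._expand_cols(1.0 / (1.0 + np.exp(-self._forward(X))))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels thresholded at 0.5; exactly 0.5 maps to active (consistent
        with the factorization model's rounding rule)."""
        p = self.predict_proba_matrix(X)
        return np.where(np.isnan(p), np.nan, (p >= 0.5).astype(float))


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fit(train: ActivityMatrix, fps: FingerprintSet, *, hidden_sizes=(256,),
        dropout: float = 0.0, train_steps: int = 2000, minibatch: int = 32,
        learning_rate: float = 0.05, on_empty_assay: str = "error", seed: int = 0):
    audit = audit_empty(train)
    if audit.empty_assays and on_empty_assay == "error":
        raise ValueError(f"assay(s) without any observed label: {audit.empty_assays[:10]}")
    fps = fps.align_to(train)
    cls = (MaskedNetClassifier if train.task_type == "classification"
           else MaskedNetRegressor)
    est = cls(hidden_sizes=hidden_sizes, dropout=dropout, train_steps=train_steps,
              minibatch=minibatch, learning_rate=learning_rate,
              on_empty_assay=on_empty_assay, random_state=seed)
    est.fit(fps.bits.astype(float), train.dense_nan())
    est.assay_ids_ = list(train.assay_ids)
    return est


def predict(model, fps_new: FingerprintSet) -> np.ndarray:
    return model.predict(fps_new.bits.astype(float))
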