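"""Bayesian probabilistic matrix factorization with compound side information.

The model approximates the (centered) activity matrix as X ~= U V^T with
Gaussian observation noise of fixed precision alpha on the observed cells:

    X_ij | u_i, v_j ~ N(u_i . v_j, 1/alpha)        (i, j) observed

Latent compound vectors carry side information through their prior mean: with
x_i the compound's 1024-bit fingerprint and beta a bits x k link matrix,

    u_i ~ N(mu_u + beta^T x_i, Lambda_u^{-1})
    v_j ~ N(mu_v,              Lambda_v^{-1})      (assays get no side information)

and (mu, Lambda) on each side follow conjugate Normal-Wishart hyperpriors.
Inference is blocked Gibbs sampling; predictions average the reconstruction
over post-burn-in samples, which for compounds never seen in training reduces
to the side-information prior mean mu_u + beta^T x — the cold-start path that
makes held-out compounds predictable at all.

The link matrix is resampled each sweep from the Gaussian conditional of a
ridge regression of U's deviations from mu_u on the fingerprint bits, with a
fixed prior precision on beta. The ridge uses unit-variance noise rather than
the current Lambda_u (which would couple latent dimensions and require
refactorizing a bits x bits system every sweep); with the bits Gram matrix
factorized once at fit time each sweep costs O(bits^2 k).

The corresponding penalized objective

    sum_{(i,j) obs} (X_ij - u_i . v_j)^2 + lambda_u ||U||_F^2 + lambda_v ||V||_F^2

is exposed as :func:`map_objective` for diagnostics.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, ClassifierMixin

from .matrix import ActivityMatrix, FingerprintSet
from .sparsify import audit_empty


def map_objective(U: np.ndarray, V: np.ndarray, Y: np.ndarray,
                  lambda_u: float = 0.0, lambda_v: float = 0.0) -> float:
    """Masked squared reconstruction error plus Frobenius penalties.

    ``Y`` holds centered observed values with NaN at unobserved cells.
    """
    R = Y - U @ V.T
    sse = float(np.nansum(R * R))
    return sse + lambda_u * float((U * U).sum()) + lambda_v * float((V * V).sum())


def _sample_normal_wishart(E: np.ndarray, rng: np.random.Generator,
                           nu0: int, kappa0: float):
    """Posterior Normal-Wishart draw of (mu, Lambda) given rows of E.

    Weakly informative base measure: W0 = I, mu0 = 0.
    """
    N, k = E.shape
    ebar = E.mean(axis=0)
    D = E - ebar
    S = D.T @ D  # N * scatter
    kappaN = kappa0 + N
    nuN = nu0 + N
    muN = (N * ebar) / kappaN  # mu0 = 0
    WN_inv = np.eye(k) + S + (kappa0 * N / kappaN) * np.outer(ebar, ebar)
    WN = np.linalg.inv(WN_inv)
    WN = (WN + WN.T) / 2.0
    Lam = stats.wishart.rvs(df=nuN, scale=WN, random_state=rng)
    Lam = np.atleast_2d(Lam)
    Lam = (Lam + Lam.T) / 2.0
    cov = np.linalg.inv(kappaN * Lam)
    mu = rng.multivariate_normal(muN, (cov + cov.T) / 2.0)
    return mu, Lam


def _sample_latents(Y0: np.ndarray, obs: np.ndarray, Other: np.ndarray,
                    prior_mean: np.ndarray, Lam: np.ndarray, alpha: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Blocked draw of all row latents given the other side's latents.

    Row i has Gaussian conditional with precision
    P_i = Lambda + alpha * sum_{j in obs_i} w_j w_j^T and mean
    P_i^{-1} (Lambda m_i + alpha * sum_j Y_ij w_j), where m_i is the prior
    mean row and w_j the other side's latents. Vectorized over rows.
    """
    n = Y0.shape[0]
    k = Other.shape[1]
    # S[i] = sum over observed j of w_j w_j^T
    S = np.einsum("ij,jk,jl->ikl", obs.astype(float), Other, Other, optimize=True)
    P = Lam[None, :, :] + alpha * S
    b = prior_mean @ Lam.T + alpha * (Y0 @ Other)  # Lam symmetric
    mean = np.linalg.solve(P, b[:, :, None])[:, :, 0]
    # noise with covariance P^{-1}: chol(P) = L, draw L^{-T} z
    Lchol = np.linalg.cholesky(P)
    z = rng.standard_normal((n, k))
    noise = np.linalg.solve(np.transpose(Lchol, (0, 2, 1)), z[:, :, None])[:, :, 0]
    return mean + noise


class MacauRegressor(RegressorMixin, BaseEstimator):
    """Multitask regressor: BPMF Gibbs sampler with fingerprint side information.

    Parameters
    ----------
    latent_dim : int, default 16
        Size k of the shared latent space.
    n_samples : int, default 120
        Post-burn-in Gibbs sweeps averaged at prediction time.
    burn_in : int, default 80
        Discarded initial sweeps.
    noise_precision : float, default 5.0
        Fixed observation precision alpha (on standardized centered values).
    link_precision : float, default 1.0
        Ridge prior precision on the fingerprint link matrix beta.
    standardize : bool, default True
        Center observed values (and scale by their standard deviation) before
        factorization; undone at prediction.
    on_empty_assay : {"error", "prune"}, default "error"
        Whether an assay with zero observed labels aborts the fit (the
        benchmark's documented failure mode) or is dropped, with NaN
        predictions for it.
    random_state : int, default 0

    Attributes
    ----------
    samples_ : list of dict
        Post-burn-in snapshots of U, V, beta and mu_u.
    value_center_, value_scale_ : float
        Affine normalization of the observed values.
    objective_trace_ : ndarray
        Masked squared error of each retained sample's reconstruction.
    """

    def __init__(self, latent_dim: int = 16, n_samples: int = 120, burn_in: int = 80,
                 noise_precision: float = 5.0, link_precision: float = 1.0,
                 standardize: bool = True, on_empty_assay: str = "error",
                 random_state: int = 0):
        self.latent_dim = latent_dim
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.noise_precision = noise_precision
        self.link_precision = link_precision
        self.standardize = standardize
        self.on_empty_assay = on_empty_assay
        self.random_state = random_state

    # -- fitting --------------------------------------------------------
    def fit(self, X: np.ndarray, Y: np.ndarray):
        """Fit on fingerprints X (n x bits) and activities Y (n x m, NaN = missing)."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2-D with matching row counts")
        if self.latent_dim < 1 or self.n_samples < 1 or self.burn_in < 0:
            raise ValueError("need latent_dim >= 1, n_samples >= 1, burn_in >= 0")
        obs = ~np.isnan(Y)
        self._validate_coverage(obs)
        col_keep = obs.any(axis=0)
        if self.on_empty_assay == "prune" and not col_keep.all():
            Y = Y[:, col_keep]
            obs = obs[:, col_keep]
        self._col_keep_ = col_keep
        self.n_assays_ = col_keep.size
        n, m = Y.shape
        k = self.latent_dim
        B = X.shape[1]
        rng = np.random.default_rng(self.random_state)

        yobs = Y[obs]
        if yobs.size == 0:
            raise ValueError("no observed labels to fit")
        self.value_center_ = float(yobs.mean())
        sd = float(yobs.std())
        self.value_scale_ = sd if (self.standardize and sd > 0) else 1.0
        Yc = (Y - self.value_center_) / self.value_scale_
        Y0 = np.where(obs, Yc, 0.0)

        alpha = float(self.noise_precision)
        lam_beta = float(self.link_precision)
        nu0 = k
        kappa0 = 1.0

        # one-time factorization of the ridge Gram matrix for the beta draw
        G = X.T @ X + lam_beta * np.eye(B)
        G_chol = sla.cho_factor(G, lower=True)
        L_beta = np.linalg.cholesky(G)  # for correlated noise on beta

        U = np.zeros((n, k))
        V = np.zeros((m, k))
        beta = np.zeros((B, k))
        Xb = X @ beta

        self.samples_ = []
        obj = []
        total = self.burn_in + self.n_samples
        for sweep in range(total):
            mu_u, Lam_u = _sample_normal_wishart(U - Xb, rng, nu0, kappa0)
            mu_v, Lam_v = _sample_normal_wishart(V, rng, nu0, kappa0)
            self._check_pd(Lam_u, sweep, "Lambda_u")
            self._check_pd(Lam_v, sweep, "Lambda_v")

            U = _sample_latents(Y0, obs, V, mu_u[None, :] + Xb, Lam_u, alpha, rng)
            V = _sample_latents(Y0.T, obs.T, U, np.broadcast_to(mu_v, (m, k)),
                                Lam_v, alpha, rng)

            # beta | U: ridge of deviations on bits, Gaussian conditional
            D = U - mu_u[None, :]
            beta_mean = sla.cho_solve(G_chol, X.T @ D)
            z = rng.standard_normal((B, k))
            beta = beta_mean + sla.solve_triangular(L_beta.T, z, lower=False)
            Xb = X @ beta

            if sweep >= self.burn_in:
                self.samples_.append(
                    {"U": U.copy(), "V": V.copy(), "beta": beta.copy(), "mu_u": mu_u.copy()}
                )
                obj.append(map_objective(U, V, Yc))
        self.objective_trace_ = np.asarray(obj)
        self.n_features_in_ = B
        self._train_obs_ = obs
        return self

    def _validate_coverage(self, obs: np.ndarray) -> None:
        empty_cols = np.where(~obs.any(axis=0))[0]
        if empty_cols.size and self.on_empty_assay == "error":
            raise ValueError(
                f"assay column(s) {empty_cols[:10].tolist()} have no observed labels; "
                "sparsified training data cannot support these tasks "
                "(set on_empty_assay='prune' to drop them)"
            )
        if self.on_empty_assay not in ("error", "prune"):
            raise ValueError("on_empty_assay must be 'error' or 'prune'")

    @staticmethod
    def _check_pd(Lam: np.ndarray, sweep: int, name: str) -> None:
        try:
            np.linalg.cholesky(Lam)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"{name} not positive definite at sweep {sweep}"
            ) from exc

    # -- prediction -----------------------------------------------------
    def _expand_cols(self, P: np.ndarray) -> np.ndarray:
        """Re-insert NaN columns for assays pruned at fit time."""
        if self._col_keep_.all():
            return P
        out = np.full((P.shape[0], self._col_keep_.size), np.nan)
        out[:, self._col_keep_] = P
        return out

    def predict(self, X: np.ndarray, return_std: bool = False):
        """Cold-start prediction for new compounds via the side-information prior.

        Each sample contributes (mu_u + beta^T x) V^T; the prediction is the
        mean over samples, mapped back to the original value scale.
        """
        self._require_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"fingerprint width {X.shape[1]} != training width {self.n_features_in_}"
            )
        preds = np.stack([
            (s["mu_u"][None, :] + X @ s["beta"]) @ s["V"].T for s in self.samples_
        ])
        mean = preds.mean(axis=0) * self.value_scale_ + self.value_center_
        if return_std:
            sd = preds.std(axis=0) * self.value_scale_
            return self._expand_cols(mean), self._expand_cols(sd)
        return self._expand_cols(mean)

    def reconstruct(self, return_std: bool = False):
        """Posterior-mean reconstruction of the training matrix (warm path)."""
        self._require_fitted()
        preds = np.stack([s["U"] @ s["V"].T for s in self.samples_])
        mean = preds.mean(axis=0) * self.value_scale_ + self.value_center_
        if return_std:
            return self._expand_cols(mean), self._expand_cols(preds.std(axis=0) * self.value_scale_)
        return self._expand_cols(mean)

    def _require_fitted(self) -> None:
        if not hasattr(self, "samples_"):
            raise RuntimeError("estimator is not fitted")


class MacauClassifier(ClassifierMixin, BaseEstimator):
    """Classification by thresholded regression: fit {0,1} labels with the
    BPMF sampler and round predictions to the nearest label (0.5 -> active).
    """

    def __init__(self, latent_dim: int = 16, n_samples: int = 120, burn_in: int = 80,
                 noise_precision: float = 5.0, link_precision: float = 1.0,
                 on_empty_assay: str = "error", random_state: int = 0):
        self.latent_dim = latent_dim
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.noise_precision = noise_precision
        self.link_precision = link_precision
        self.on_empty_assay = on_empty_assay
        self.random_state = random_state

    def fit(self, X: np.ndarray, Y: np.ndarray):
        Y = np.asarray(Y, dtype=float)
        vals = Y[~np.isnan(Y)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("classification labels must be in {0, 1}")
        self.regressor_ = MacauRegressor(
            latent_dim=self.latent_dim, n_samples=self.n_samples, burn_in=self.burn_in,
            noise_precision=self.noise_precision, link_precision=self.link_precision,
            standardize=True, on_empty_assay=self.on_empty_assay,
            random_state=self.random_state,
        ).fit(X, Y)
        self.classes_ = np.array([0.0, 1.0])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.regressor_.predict(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return round_to_labels(self.decision_function(X))

    def reconstruct_labels(self) -> np.ndarray:
        return round_to_labels(self.regressor_.reconstruct())


def round_to_labels(pred: np.ndarray) -> np.ndarray:
    """Round to the nearest label and clamp to {0, 1}; exact 0.5 rounds to active.

    NaN (pruned assays) propagates.
    """
    pred = np.asarray(pred, dtype=float)
    out = np.where(pred >= 0.5, 1.0, 0.0)
    return np.where(np.isnan(pred), np.nan, out)


# ---------------------------------------------------------------------------
# Functional surface over the estimators
# ---------------------------------------------------------------------------

def fit(train: ActivityMatrix, fps: FingerprintSet, *, latent_dim: int = 16,
        n_samples: int = 120, burn_in: int = 80, noise_precision: float = 5.0,
        link_precision: float = 1.0, on_empty_assay: str = "error",
        seed: int = 0):
    """Fit the matching estimator on an ActivityMatrix + aligned fingerprints."""
    audit = audit_empty(train)
    if audit.empty_assays and on_empty_assay == "error":
        raise ValueError(
            f"assay(s) without any observed label: {audit.empty_assays[:10]}"
        )
    fps = fps.align_to(train)
    cls = MacauClassifier if train.task_type == "classification" else MacauRegressor
    est = cls(latent_dim=latent_dim, n_samples=n_samples, burn_in=burn_in,
              noise_precision=noise_precision, link_precision=link_precision,
              on_empty_assay=on_empty_assay, random_state=seed)
    est.fit(fps.bits.astype(float), train.dense_nan())
    est.assay_ids_ = list(train.assay_ids)
    est.compound_ids_ = list(train.compound_ids)
    return est


def predict(model, fps_new: FingerprintSet, assay_ids: list[str] | None = None) -> np.ndarray:
    """Predict the activity profile for new compounds; optionally a subset of assays."""
    P = model.predict(fps_new.bits.astype(float))
    if assay_ids is None:
        return P
    pos = {a: i for i, a in enumerate(model.assay_ids_)}
    missing = [a for a in assay_ids if a not in pos]
    if missing:
        raise ValueError(f"unknown assay id(s): {missing[:10]}")
    return P[:, [pos[a] for a in assay_ids]]
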