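"""Gibbs-sampled matrix factorization: objective, recovery, prediction rules."""

import numpy as np
import pytest

import sparsemt.factorization as fz
from sparsemt.factorization import (
    MacauClassifier,
    MacauRegressor,
    map_objective,
    round_to_labels,
)
from sparsemt.matrix import ActivityMatrix, FingerprintSet


def _rank1_problem(n=6, m=4, seed=0, holdout=0.3):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 1))
    v = rng.normal(size=(m, 1))
    Y = u @ v.T
    hold = rng.random(Y.shape) < holdout
    Ytr = Y.copy()
    Ytr[hold] = np.nan
    # ensure no empty assay
    for j in np.where(np.isnan(Ytr).all(axis=0))[0]:
        Ytr[0, j] = Y[0, j]
        hold[0, j] = False
    X = (rng.random((n, 32)) < 0.3).astype(float)
    X[X.sum(axis=1) == 0, 0] = 1
    return X, Y, Ytr, hold


class TestMapObjective:
    def test_zero_factors_give_sum_of_squares(self):
        Y = np.array([[1.0, np.nan], [2.0, 3.0]])
        assert map_objective(np.zeros((2, 2)), np.zeros((2, 2)), Y) == 1 + 4 + 9

    def test_exact_factorization_is_zero(self):
        rng = np.random.default_rng(0)
        U, V = rng.normal(size=(5, 2)), rng.normal(size=(4, 2))
        assert map_objective(U, V, U @ V.T) == pytest.approx(0.0, abs=1e-18)

    def test_matches_hand_summation(self):
        rng = np.random.default_rng(1)
        U, V = rng.normal(size=(4, 2)), rng.normal(size=(3, 2))
        Y = rng.normal(size=(4, 3))
        Y[1, 2] = np.nan
        lu, lv = 0.3, 0.7
        total = lu * (U ** 2).sum() + lv * (V ** 2).sum()
        for i in range(4):
            for j in range(3):
                if not np.isnan(Y[i, j]):
                    total += (Y[i, j] - U[i] @ V[j]) ** 2
        assert map_objective(U, V, Y, lu, lv) == pytest.approx(total)


class TestFit:
    def test_rank1_noiseless_recovery(self):
        X, Y, Ytr, hold = _rank1_problem()
        est = MacauRegressor(latent_dim=2, n_samples=150, burn_in=100,
                             noise_precision=100.0, random_state=0)
        est.fit(X, Ytr)
        R = est.reconstruct()
        rmsd = np.sqrt(np.mean((R[hold] - Y[hold]) ** 2))
        assert rmsd < 0.05 * np.ptp(Y)

    def test_deterministic_given_seed(self):
        X, _, Ytr, _ = _rank1_problem(seed=3)
        a = MacauRegressor(latent_dim=2, n_samples=5, burn_in=5, random_state=7).fit(X, Ytr)
        b = MacauRegressor(latent_dim=2, n_samples=5, burn_in=5, random_state=7).fit(X, Ytr)
        for sa, sb in zip(a.samples_, b.samples_):
            assert np.array_equal(sa["U"], sb["U"])
            assert np.array_equal(sa["beta"], sb["beta"])

    def test_empty_assay_errors_by_default(self):
        X, _, Ytr, _ = _rank1_problem()
        Ytr[:, 1] = np.nan
        with pytest.raises(ValueError, match="no observed labels"):
            MacauRegressor(latent_dim=2, n_samples=2, burn_in=1).fit(X, Ytr)

    def test_empty_assay_pruned_when_requested(self):
        X, _, Ytr, _ = _rank1_problem()
        Ytr[:, 1] = np.nan
        est = MacauRegressor(latent_dim=2, n_samples=3, burn_in=2,
                             on_empty_assay="prune", random_state=0).fit(X, Ytr)
        P = est.predict(X)
        assert np.isnan(P[:, 1]).all()
        assert np.isfinite(P[:, 0]).all()

    def test_objective_trend_non_increasing(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=(40, 3))
        v = rng.normal(size=(20, 3))
        Y = u @ v.T + 0.1 * rng.normal(size=(40, 20))
        X = (rng.random((40, 64)) < 0.3).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        est = MacauRegressor(latent_dim=4, n_samples=40, burn_in=0,
                             random_state=0).fit(X, Y)
        first = np.median(est.objective_trace_[:10])
        last = np.median(est.objective_trace_[-10:])
        assert last <= first


class TestPredict:
    def test_single_sample_prediction_equals_reconstruction(self):
        X, _, Ytr, _ = _rank1_problem(seed=5)
        est = MacauRegressor(latent_dim=2, n_samples=1, burn_in=10,
                             random_state=1).fit(X, Ytr)
        s = est.samples_[0]
        manual = (s["U"] @ s["V"].T) * est.value_scale_ + est.value_center_
        assert np.allclose(est.reconstruct(), manual)

    def test_two_sample_prediction_is_hand_computed_average(self):
        X, _, Ytr, _ = _rank1_problem(seed=6)
        est = MacauRegressor(latent_dim=2, n_samples=2, burn_in=10,
                             random_state=2).fit(X, Ytr)
        manual = np.mean([
            (s["mu_u"][None, :] + X @ s["beta"]) @ s["V"].T for s in est.samples_
        ], axis=0) * est.value_scale_ + est.value_center_
        assert np.allclose(est.predict(X), manual)

    def test_constant_matrix_predicts_the_constant(self):
        rng = np.random.default_rng(0)
        X = (rng.random((8, 16)) < 0.4).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        Y = np.full((8, 3), 42.0)
        est = MacauRegressor(latent_dim=2, n_samples=100, burn_in=20,
                             random_state=0).fit(X, Y)
        # centering absorbs the constant; residual factors only carry
        # posterior noise of order 1/sqrt(noise_precision * cells)
        assert np.allclose(est.reconstruct(), 42.0, atol=0.5)

    def test_fingerprint_width_mismatch_rejected(self):
        X, _, Ytr, _ = _rank1_problem()
        est = MacauRegressor(latent_dim=2, n_samples=2, burn_in=1,
                             random_state=0).fit(X, Ytr)
        with pytest.raises(ValueError, match="width"):
            est.predict(X[:, :10])

    def test_reconstruction_invariant_to_latent_rotation(self):
        """Predictions are compared, never raw latents: rotating U and V
        jointly leaves every reconstruction unchanged."""
        rng = np.random.default_rng(4)
        U, V = rng.normal(size=(6, 3)), rng.normal(size=(5, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert np.allclose(U @ V.T, (U @ Q) @ (V @ Q).T)


class TestSideInformation:
    def test_huge_link_precision_disables_side_information(self):
        """With the link ridge precision driven to infinity, beta -> 0 and the
        model reduces to plain BPMF: reconstructions with real vs random
        fingerprints coincide."""
        X, _, Ytr, _ = _rank1_problem(seed=8)
        rng = np.random.default_rng(0)
        Xnoise = (rng.random(X.shape) < 0.3).astype(float)
        Xnoise[Xnoise.sum(axis=1) == 0, 0] = 1
        recon = []
        for Xi in (X, Xnoise):
            est = MacauRegressor(latent_dim=2, n_samples=60, burn_in=60,
                                 link_precision=1e12, random_state=5).fit(Xi, Ytr)
            recon.append(est.reconstruct())
        scale = np.ptp(Ytr[~np.isnan(Ytr)])
        assert np.nanmax(np.abs(recon[0] - recon[1])) < 0.15 * scale


class TestClassification:
    @pytest.mark.parametrize("pred,label", [
        (0.49, 0.0), (0.51, 1.0), (-0.3, 0.0), (1.7, 1.0), (0.5, 1.0),
    ])
    def test_rounding_rule(self, pred, label):
        assert round_to_labels(np.array([pred]))[0] == label

    def test_classifier_fits_binary_panel(self):
        rng = np.random.default_rng(0)
        X = (rng.random((30, 32)) < 0.3).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        score = X[:, :4].sum(axis=1)
        Y = np.stack([(score > np.median(score)).astype(float)] * 3, axis=1)
        Y[0, 0] = 1 - Y[0, 0]  # break constant columns ties
        est = MacauClassifier(latent_dim=2, n_samples=30, burn_in=20,
                              random_state=0).fit(X, Y)
        P = est.predict(X)
        assert set(np.unique(P)) <= {0.0, 1.0}
        assert (P == Y).mean() > 0.7

    def test_non_binary_labels_rejected(self):
        X = np.ones((4, 8))
        Y = np.array([[0.0], [1.0], [2.0], [0.0]])
        with pytest.raises(ValueError, match="0, 1"):
            MacauClassifier(latent_dim=1, n_samples=1, burn_in=0).fit(X, Y)


class TestFunctionalSurface:
    def test_fit_predict_with_assay_subset(self, full_matrix_10x10):
        rng = np.random.default_rng(0)
        bits = (rng.random((10, 32)) < 0.3).astype(np.uint8)
        bits[bits.sum(axis=1) == 0, 0] = 1
        fps = FingerprintSet(bits, full_matrix_10x10.compound_ids)
        model = fz.fit(full_matrix_10x10, fps, latent_dim=2, n_samples=5,
                       burn_in=5, seed=0)
        P = fz.predict(model, fps, assay_ids=["a2", "a0"])
        assert P.shape == (10, 2)
        with pytest.raises(ValueError, match="unknown assay"):
            fz.predict(model, fps, assay_ids=["zz"])
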