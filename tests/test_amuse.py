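"""Second-order ICA step: whitening + lagged-covariance rotation, labeling."""

import numpy as np
import pytest

from dermabss.amuse import amuse_unmix, label_melanin_shading
from dermabss.metrics import sir


def _exact_hypothesis_sources(rng, n, lag=1):
    """Two signals exactly satisfying the AMUSE moment conditions in-sample.

    Whiten two autocorrelated draws exactly, then rotate into the eigenbasis
    of the symmetrized lag covariance: the result has identity covariance and
    a diagonal lagged covariance with (generically) distinct eigenvalues.
    """
    raw = np.cumsum(rng.standard_normal((2, n)), axis=1)
    raw[1] = rng.standard_normal(n)
    raw -= raw.mean(axis=1, keepdims=True)
    C0 = raw @ raw.T / n
    w, E = np.linalg.eigh(C0)
    W = (E / np.sqrt(w)).T
    Z = W @ raw
    Cv = Z[:, lag:] @ Z[:, :-lag].T / (n - lag)
    lam, V = np.linalg.eigh(0.5 * (Cv + Cv.T))
    return V.T @ Z


def _offdiag_ratio(G):
    G = np.abs(G)
    if G[0, 0] + G[1, 1] < G[0, 1] + G[1, 0]:
        G = G[::-1]     # undo permutation
    return max(G[0, 1] / G[0, 0], G[1, 0] / G[1, 1])


class TestAmuseUnmix:
    def test_exact_model_recovery_to_machine_precision(self):
        rng = np.random.default_rng(0)
        S = _exact_hypothesis_sources(rng, 4096)
        M = np.array([[0.18, 0.23], [0.07, 0.24]])
        res = amuse_unmix(M @ S)
        assert _offdiag_ratio(res.U @ M) < 1e-8
        np.testing.assert_array_equal(res.Y, res.U @ (M @ S))
        assert abs(res.Y_centered.mean(axis=1)).max() < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_identity_mixing_sources_of_distinct_lag_correlation(self, seed):
        # sinusoid (lag-1 autocorrelation ~ +1) vs differenced noise (~ -1/2)
        rng = np.random.default_rng(seed)
        n = 2 ** 14
        t = np.arange(n)
        s_smooth = np.sin(2 * np.pi * t / 256 + rng.uniform(0, 2 * np.pi))
        w = rng.standard_normal(n + 1)
        res = amuse_unmix(np.vstack([s_smooth, w[1:] - w[:-1]]))
        assert _offdiag_ratio(res.U) < 1e-2

    def test_random_mixing_high_sir_recovery(self):
        from scipy.ndimage import gaussian_filter1d
        rng = np.random.default_rng(7)
        n = 128 * 128
        S = np.vstack([gaussian_filter1d(rng.standard_normal(n), 10.0),
                       gaussian_filter1d(rng.standard_normal(n), 1.0)])
        M = rng.uniform(0.1, 1.0, size=(2, 2))
        res = amuse_unmix(M @ S)
        G = np.abs(res.U @ M)
        order = (0, 1) if G[0, 0] * G[1, 1] > G[0, 1] * G[1, 0] else (1, 0)
        sirs = [sir(S[j], res.Y[i]) for j, i in zip((0, 1), order)]
        assert np.mean(sirs) > 30.0

    def test_equal_spectra_trigger_identifiability_warning(self):
        t = np.arange(8192)
        S = np.vstack([np.sin(2 * np.pi * t / 64),
                       np.cos(2 * np.pi * t / 64)])
        X = np.array([[1.0, 0.4], [0.3, 1.0]]) @ S
        with pytest.warns(RuntimeWarning, match="identifiability"):
            res = amuse_unmix(X)
        assert res.eigen_gap < 1e-3

    def test_collinear_mixtures_rejected(self):
        x = np.random.default_rng(1).standard_normal(512)
        with pytest.raises(ValueError, match="collinear"):
            amuse_unmix(np.vstack([x, 2.0 * x]))

    def test_scale_handling_through_whitening(self):
        """Whitening normalizes the estimates, so Y is invariant to a common
        positive rescaling of the mixtures (U absorbs the factor)."""
        rng = np.random.default_rng(2)
        S = _exact_hypothesis_sources(rng, 2048)
        X = np.array([[0.5, 0.2], [0.1, 0.6]]) @ S
        a = amuse_unmix(X)
        b = amuse_unmix(3.7 * X)
        np.testing.assert_allclose(np.abs(b.U * 3.7), np.abs(a.U), atol=1e-10)
        np.testing.assert_allclose(np.abs(b.Y), np.abs(a.Y), atol=1e-8)

    def test_lag_bounds_checked(self):
        X = np.random.default_rng(0).standard_normal((2, 64))
        with pytest.raises(ValueError):
            amuse_unmix(X, lag=0)
        with pytest.raises(ValueError):
            amuse_unmix(X, lag=64)


class TestLabeling:
    @staticmethod
    def _result(maps):
        from dermabss.amuse import UnmixingResult
        Y = np.vstack([m.ravel() for m in maps])
        return UnmixingResult(U=np.eye(2), Y=Y,
                              Y_centered=Y - Y.mean(axis=1, keepdims=True),
                              eigen_gap=1.0, eigenvalues=np.array([0.0, 1.0]))

    def test_vignette_labeled_shading_blob_labeled_melanin(self):
        rr, cc = np.mgrid[0:32, 0:32].astype(float)
        blob = np.exp(-(((rr - 16) ** 2 + (cc - 16) ** 2) / 36.0))
        vignette = np.hypot(rr - 16, cc - 16) / 22.6
        src, diag = label_melanin_shading(self._result([blob, vignette]),
                                          (32, 32))
        np.testing.assert_allclose(src.shading, vignette.ravel())
        np.testing.assert_allclose(src.melanin, blob.ravel())
        assert diag["shading_component"] == 1

    def test_negative_mean_map_is_sign_flipped(self):
        rr, cc = np.mgrid[0:32, 0:32].astype(float)
        blob = np.exp(-(((rr - 16) ** 2 + (cc - 16) ** 2) / 36.0))
        vignette = np.hypot(rr - 16, cc - 16) / 22.6
        src, _ = label_melanin_shading(self._result([-blob, vignette]),
                                       (32, 32))
        assert src.melanin.mean() >= 0
        np.testing.assert_allclose(src.melanin, blob.ravel())

    def test_ambiguous_border_scores_rejected(self):
        m = np.random.default_rng(0).uniform(0.1, 1.0, size=(16, 16))
        with pytest.raises(ValueError, match="ambiguous"):
            label_melanin_shading(self._result([m, m]), (16, 16))

    def test_simulated_ground_truth_labeled_correctly_30_runs(
            self, default_config):
        from dermabss.simulator import simulate_sources
        hits = 0
        for seed in range(30):
            S = simulate_sources(default_config,
                                 np.random.default_rng(seed))
            src, _ = label_melanin_shading(
                self._result([S.map2d("melanin"), S.map2d("shading")]),
                S.shape)
            hits += np.array_equal(src.shading, S.shading)
        assert hits == 30
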