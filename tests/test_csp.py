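"""CSP correctness: closed forms, brute-force oracles, feature algebra."""

import numpy as np
import pytest

import strokebci as sb
from strokebci.csp import (FilterBankCSP, _class_covariances,
                           batch_size_invariant, encode_labels,
                           extract_features, spatial_patterns)
from strokebci.preprocess import EpochedBandTensor


def _orthonormal_rows(rng, n_rows, n_samples):
    """Zero-mean rows, mutually orthogonal, each of norm sqrt(n_samples)."""
    m = rng.standard_normal((n_samples, n_rows + 1))
    m[:, 0] = 1.0  # absorb the constant so the rest is zero-mean
    q, _ = np.linalg.qr(m)
    return q[:, 1:].T * np.sqrt(n_samples)


def tensor_from_covariances(cov_move, cov_rest, n_each=2, n_samples=64,
                            seed=0):
    """Trials whose centered sample covariance equals the target exactly."""
    rng = np.random.default_rng(seed)
    n_ch = cov_move.shape[0]
    trials, labels = [], []
    for cov, lab in ((cov_move, "move"), (cov_rest, "rest")):
        L = np.linalg.cholesky(cov)
        for _ in range(n_each):
            basis = _orthonormal_rows(rng, n_ch, n_samples)
            trials.append((L @ basis)[None])  # one band
            labels.append(lab)
    segments = np.stack(trials)
    return EpochedBandTensor(segments, np.array(labels), ((8.0, 12.0),),
                             (0.0, n_samples), 64.0, None)


class TestTwoChannelClosedForm:
    """diag(4,1) vs diag(1,4): generalized eigenvalues are 0.8 and 0.2."""

    def setup_method(self):
        self.tensor = tensor_from_covariances(np.diag([4.0, 1.0]),
                                              np.diag([1.0, 4.0]))
        self.model = FilterBankCSP().fit(self.tensor)

    def test_whitened_eigenvalues(self):
        assert np.allclose(self.model.eigenvalues_[0], [0.8, 0.2], atol=1e-10)

    def test_first_filter_isolates_channel_one(self):
        w1 = self.model.filters_[0][:, 0]
        assert abs(w1[1] / w1[0]) < 1e-8

    def test_first_pattern_aligned_with_channel_one_axis(self):
        p = spatial_patterns(self.model)[0][:, 0]
        assert abs(p[1] / p[0]) < 1e-8


class TestFitInvariants:
    def test_whitening_identity(self, fitted_csp, healthy_tensor):
        y = encode_labels(healthy_tensor.labels)
        cov_m, cov_r = _class_covariances(healthy_tensor, y)
        for b, w in enumerate(fitted_csp.filters_):
            composite = cov_m[b] + cov_r[b]
            assert np.allclose(w.T @ composite @ w, np.eye(w.shape[0]),
                               atol=1e-6)

    def test_eigenvalue_complementarity(self, fitted_csp, healthy_tensor):
        y = encode_labels(healthy_tensor.labels)
        _, cov_r = _class_covariances(healthy_tensor, y)
        for b, w in enumerate(fitted_csp.filters_):
            rest_vals = np.diag(w.T @ cov_r[b] @ w)
            assert np.allclose(fitted_csp.eigenvalues_[b] + rest_vals, 1.0,
                               atol=1e-6)

    def test_identical_class_covariances_give_half_eigenvalues(self):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        model = FilterBankCSP().fit(tensor_from_covariances(cov, cov))
        assert np.allclose(model.eigenvalues_[0], 0.5, atol=1e-10)

    def test_sign_convention_is_deterministic(self):
        t = tensor_from_covariances(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]))
        a = FilterBankCSP().fit(t).filters_
        b = FilterBankCSP().fit(t).filters_
        assert np.array_equal(a, b)
        for w in a[0].T:
            assert w[np.abs(w).argmax()] > 0

    def test_one_class_absent_rejected(self):
        t = tensor_from_covariances(np.eye(2), np.eye(2))
        t.labels[:] = "move"
        with pytest.raises(ValueError, match="rest"):
            FilterBankCSP().fit(t)

    def test_singular_composite_suggests_ridge(self):
        # every trial is the same rank-1 signal -> composite covariance rank 1
        segs = np.ones((4, 1, 2, 8)) * np.sin(np.arange(8))
        t = EpochedBandTensor(segs, np.array(["move", "rest"] * 2),
                              ((8.0, 12.0),), (0.0, 8), 64.0, None)
        with pytest.raises(ValueError, match="ridge|singular"):
            FilterBankCSP().fit(t)


class TestBruteForceOracle:
    """Implementation vs direct eig of (Σm+Σr)⁻¹ Σm on random instances."""

    @pytest.mark.parametrize("n_ch", [2, 3, 4])
    def test_matches_generalized_eigenproblem(self, n_ch, rng):
        for trial in range(10):
            a = rng.standard_normal((n_ch, 2 * n_ch))
            b = rng.standard_normal((n_ch, 2 * n_ch))
            cov_m = a @ a.T / (2 * n_ch)
            cov_r = b @ b.T / (2 * n_ch)
            tensor = tensor_from_covariances(cov_m, cov_r,
                                             seed=1000 + trial)
            model = FilterBankCSP().fit(tensor)
            # oracle path: plain (non-symmetric) eigendecomposition,
            # after the same per-trial trace normalization
            y = encode_labels(tensor.labels)
            sm, sr = _class_covariances(tensor, y)
            vals = np.linalg.eigvals(np.linalg.inv(sm[0] + sr[0]) @ sm[0])
            vals = np.sort(vals.real)[::-1]
            assert np.allclose(model.eigenvalues_[0], vals, atol=1e-8)
            # filters diagonalize both class covariances
            w = model.filters_[0]
            off = w.T @ sm[0] @ w - np.diag(model.eigenvalues_[0])
            assert np.abs(off).max() < 1e-8


class TestProjectionAndFeatures:
    def test_identity_projection_returns_input(self, healthy_tensor):
        model = FilterBankCSP().fit(healthy_tensor)
        model.filters_ = np.broadcast_to(
            np.eye(32), model.filters_.shape).copy()
        z = model.transform_trials(healthy_tensor)
        assert np.array_equal(z, healthy_tensor.segments)

    def test_projection_preserves_shape(self, fitted_csp, healthy_tensor):
        z = fitted_csp.transform_trials(healthy_tensor)
        assert z.shape == healthy_tensor.segments.shape

    def test_pattern_trial_concentrates_energy(self, fitted_csp):
        patterns = spatial_patterns(fitted_csp)
        j = 3
        s = np.sin(2 * np.pi * 10 * np.arange(256) / 256.0)
        trial = np.einsum("c,s->cs", patterns[0][:, j], s)
        z = np.einsum("cj,cs->js", fitted_csp.filters_[0], trial)
        energy = z.var(axis=1)
        assert energy[j] / energy.sum() > 1 - 1e-9

    def test_biorthogonality(self, fitted_csp):
        patterns = spatial_patterns(fitted_csp)
        for p, w in zip(patterns, fitted_csp.filters_):
            assert np.allclose(p.T @ w, np.eye(32), atol=1e-6)

    def test_feature_columns_exp_sum_to_one(self, healthy_features):
        sums = np.exp(healthy_features.V).sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_feature_vector_length_is_bands_times_channels(self,
                                                           healthy_features):
        assert healthy_features.V.shape == (40, 9 * 32)
        assert healthy_features.column_index[0] == (0, 0)
        assert healthy_features.column_index[-1] == (8, 31)

    def test_two_trial_proportional_variance(self):
        model = FilterBankCSP()
        model.bands_ = ((8.0, 12.0),)
        model.column_index_ = [(0, 0)]
        model.feature_norm = "trials"
        # component variances 1 and 3 exactly
        z = np.stack([
            np.array([[[1.0, -1.0] * 8]]),
            np.sqrt(3.0) * np.array([[[1.0, -1.0] * 8]]),
        ])
        f = model._features_from_projected(z, None)
        assert np.allclose(f.V[:, 0], [np.log(1 / 4), np.log(3 / 4)])

    def test_single_trial_features_are_zero(self):
        model = FilterBankCSP()
        model.bands_ = ((8.0, 12.0),)
        model.column_index_ = [(0, 0)]
        model.feature_norm = "trials"
        z = np.array([[[[2.0, -2.0] * 8]]])
        f = model._features_from_projected(z, None)
        assert np.allclose(f.V, 0.0)

    def test_batch_size_invariant_shift(self, healthy_features):
        shifted = batch_size_invariant(healthy_features)
        assert np.allclose(shifted.V - healthy_features.V, np.log(40))

    def test_across_component_normalization_option(self, healthy_tensor):
        model = FilterBankCSP(feature_norm="components").fit(healthy_tensor)
        f = model.transform(healthy_tensor)
        per_band = np.exp(f.V).reshape(40, 9, 32).sum(axis=2)
        assert np.allclose(per_band, 1.0, atol=1e-9)

    def test_channel_order_mismatch_rejected(self, fitted_csp,
                                             healthy_tensor):
        names = list(sb.biosemi32().names)
        names[0], names[1] = names[1], names[0]
        shuffled = sb.ChannelSet(tuple(names), sb.biosemi32().midline_flags,
                                 sb.biosemi32().mirror_pairs)
        bad = EpochedBandTensor(healthy_tensor.segments,
                                healthy_tensor.labels, healthy_tensor.bands,
                                healthy_tensor.window, healthy_tensor.fs,
                                shuffled)
        with pytest.raises(ValueError, match="channel order"):
            fitted_csp.transform(bad)

    def test_zero_variance_component_named(self, fitted_csp):
        z = np.zeros((2, 9, 32, 16))  # flat signal: zero variance everywhere
        with pytest.raises(ValueError, match="band"):
            fitted_csp._features_from_projected(z, None)
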