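"""Covariance-pooling operator: examples, properties, and oracle agreement."""

import numpy as np
import pytest

from robustfood.egcp import (EGCPConfig, dynamic_scaling, egcp_transform,
                             enhance_eigenvalues, normalize_features,
                             regularize_and_decompose,
                             scaling_factor_closed_form, weighted_covariance)
from robustfood.tensor import Tensor

from .oracles import egcp_reference

CFG = EGCPConfig(epsilon=1e-5)


class TestNormalizeFeatures:
    def test_constant_channel_maps_to_zero(self):
        x = np.full((1, 3, 3), 5.0)
        out = normalize_features(x, CFG)
        assert np.allclose(out.values.data, 0.0)

    def test_symmetric_pair(self):
        x = np.array([[[-1.0, 1.0]]])
        out = normalize_features(x, EGCPConfig(epsilon=1e-12))
        assert np.allclose(out.values.data, [[[-1.0, 1.0]]], atol=1e-6)
        assert np.allclose(out.mu.data, 0.0)
        assert np.allclose(out.sigma2.data, 1.0)

    def test_statistics_match_direct_loop(self, rng):
        x = rng.normal(2.0, 3.0, size=(4, 3, 3))
        out = normalize_features(x, CFG)
        ref = egcp_reference(x, CFG.epsilon)
        np.testing.assert_allclose(out.mu.data, ref["mu"], atol=1e-12)
        np.testing.assert_allclose(out.sigma2.data, ref["sigma2"], atol=1e-12)
        np.testing.assert_allclose(out.weights.data, ref["weights"], rtol=1e-12)
        # each channel: mean ~ 0, variance = sigma2/(sigma2+eps)
        vals = out.values.data
        assert np.abs(vals.mean(axis=(1, 2))).max() < 1e-9
        expect_var = ref["sigma2"] / (ref["sigma2"] + CFG.epsilon)
        np.testing.assert_allclose(vals.var(axis=(1, 2)), expect_var, rtol=1e-9)

    def test_nonfinite_input_names_channel(self):
        x = np.zeros((3, 2, 2))
        x[1, 0, 0] = np.nan
        with pytest.raises(ValueError, match="channel 1"):
            normalize_features(x, CFG)


class TestWeightedCovariance:
    def test_single_spatial_position_gives_zero(self):
        x = np.array([[[3.0]], [[7.0]]])
        P = weighted_covariance(normalize_features(x, CFG))
        assert np.allclose(P.entries.data, 0.0)

    def test_identical_channels_rank_one(self, rng):
        row = rng.normal(size=(1, 2, 4))
        x = np.concatenate([row, row], axis=0)
        P = weighted_covariance(normalize_features(x, CFG)).entries.data
        # explicit outer-product oracle: equal channels => all entries equal
        # up to the sqrt(w_i w_j) scaling (weights are equal here)
        assert np.allclose(P[0, 0], P[1, 1], rtol=1e-10)
        assert np.allclose(P[0, 1], P[0, 0], rtol=1e-10)
        assert np.linalg.matrix_rank(P, tol=1e-10) == 1

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=(6, 8, 8))
        P = weighted_covariance(normalize_features(x, CFG)).entries.data
        ref = egcp_reference(x, CFG.epsilon)
        np.testing.assert_allclose(P, ref["P"], atol=1e-10)

    def test_higher_variance_channel_gets_smaller_weight(self, rng):
        x = np.stack([rng.normal(0, 0.5, size=(5, 5)),
                      rng.normal(0, 3.0, size=(5, 5))])
        out = normalize_features(x, CFG)
        assert out.weights.data[0] > out.weights.data[1]


class TestRegularizeAndDecompose:
    def test_identity_input(self):
        st = regularize_and_decompose(np.eye(3), CFG)
        assert np.allclose(st.lambdas_reg.data, 1.0 + CFG.epsilon)
        U = st.U.data
        assert np.allclose(U.T @ U, np.eye(3), atol=1e-10)

    def test_diagonal_input(self):
        st = regularize_and_decompose(np.diag([2.0, 0.5]), CFG)
        np.testing.assert_allclose(sorted(st.lambdas_reg.data, reverse=True),
                                   [2.0 + 1e-5, 0.5 + 1e-5], rtol=1e-12)

    def test_reconstruction(self, rng):
        A = rng.normal(size=(5, 5))
        P = (A + A.T) / 2
        st = regularize_and_decompose(P, CFG)
        P_reg = P + CFG.epsilon * np.eye(5)
        recon = st.U.data @ np.diag(st.lambdas.data) @ st.U.data.T
        err = np.linalg.norm(recon - P_reg) / np.linalg.norm(P_reg)
        assert err < 1e-6

    def test_rejects_asymmetric(self, rng):
        P = rng.normal(size=(4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            regularize_and_decompose(P, CFG)

    def test_floor_holds_on_random_inputs(self, rng):
        for _ in range(100):
            x = rng.normal(size=(4, 3, 3))
            st = regularize_and_decompose(
                weighted_covariance(normalize_features(x, CFG)), CFG)
            assert st.lambdas_reg.data.min() >= CFG.epsilon - 1e-15


class TestEnhanceEigenvalues:
    @pytest.mark.parametrize("lam, expected", [
        (0.0, 0.0),
        (np.e - 1.0, 1.0),
        (1.0, np.log(2.0)),
    ])
    def test_analytic_values(self, lam, expected):
        out = enhance_eigenvalues(np.array([lam]))
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            enhance_eigenvalues(np.array([-0.1]))

    def test_relative_amplification_decreasing(self):
        # log(1+lam)/lam strictly decreases: small eigenvalues gain most
        grid = np.logspace(-4, 2, 1000)
        gain = np.log1p(grid) / grid
        assert np.all(np.diff(gain) < 0)


class TestDynamicScaling:
    def test_zero_spectrum(self):
        U = np.eye(3)
        S_mat, Q, S_F = dynamic_scaling(U, np.zeros(3))
        assert np.allclose(S_mat.data, np.eye(3))
        assert np.allclose(Q.data, 0.0)
        assert np.allclose(S_F.data, 0.0)

    def test_scalar_case(self):
        _, _, S_F = dynamic_scaling(np.eye(1), np.array([1.0]))
        assert np.allclose(S_F.data, np.exp(-1.0), atol=1e-12)

    def test_two_dim_matches_explicit_assembly(self):
        lam = np.array([1.0, 1.0])
        S_mat, Q, S_F = dynamic_scaling(np.eye(2), lam)
        assert np.allclose(S_F.data, np.sqrt(2.0 * np.exp(-2.0)), atol=1e-12)
        Q_explicit = np.diag(np.sqrt(lam) * np.exp(-lam))
        assert np.allclose(Q.data, Q_explicit, atol=1e-12)
        assert np.allclose(S_F.data, np.linalg.norm(Q_explicit, "fro"), atol=1e-12)

    def test_closed_form_on_random_eigenstates(self, rng):
        for _ in range(100):
            D = int(rng.integers(2, 7))
            M = rng.normal(size=(D, D))
            U, _ = np.linalg.qr(M)
            lam = rng.uniform(0.0, 3.0, size=D)
            _, Q, S_F = dynamic_scaling(U, lam)
            closed = scaling_factor_closed_form(lam)
            assert abs(np.linalg.norm(Q.data, "fro") - closed) < 1e-8
            assert abs(S_F.item() - closed) < 1e-8

    def test_rejects_negative_enhanced_eigenvalue(self):
        with pytest.raises(ValueError):
            dynamic_scaling(np.eye(2), np.array([0.5, -0.1]))


class TestEGCPTransform:
    def test_all_zero_input_hand_trace(self):
        # scalar hand trace: P = 0, P_reg = eps I, lam_en = log(1+eps),
        # A = (S_F+1) sqrt(log(1+eps)) I
        eps = CFG.epsilon
        res = egcp_transform(np.zeros((3, 4, 4)), CFG)
        lam_en = np.log1p(eps)
        s_f = np.sqrt(3 * lam_en * np.exp(-2 * lam_en))
        expect_A = (s_f + 1.0) * np.sqrt(lam_en) * np.eye(3)
        np.testing.assert_allclose(res.A.data, expect_A, atol=1e-10)
        np.testing.assert_allclose(res.S_F.item(), s_f, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        D = int(rng.integers(2, 9))
        H, W = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        x = rng.normal(size=(D, H, W)) * rng.uniform(0.5, 2.0)
        res = egcp_transform(x, CFG)
        ref = egcp_reference(x, CFG.epsilon)
        scale = max(np.abs(ref["a_flat"]).max(), 1e-12)
        assert np.abs(res.a_flat.data - ref["a_flat"]).max() / scale < 1e-6
        assert abs(res.S_F.item() - ref["S_F"]) / max(ref["S_F"], 1e-12) < 1e-6

    def test_replication_invariance(self, rng):
        x = rng.normal(size=(4, 3, 3))
        tiled = np.tile(x, (1, 2, 2))
        a1 = egcp_transform(x, CFG).A.data
        a2 = egcp_transform(tiled, CFG).A.data
        np.testing.assert_allclose(a1, a2, atol=1e-8)

    def test_symmetry_and_psd(self, rng):
        x = rng.normal(size=(5, 6, 6))
        res = egcp_transform(x, CFG)
        for M in (res.P_en.data, res.S_mat.data, res.A.data):
            assert np.abs(M - M.T).max() < 1e-6
        assert np.linalg.eigvalsh(res.A.data).min() >= -1e-10
        assert res.S_F.item() >= 0.0

    def test_conjugation_equivariance(self, rng):
        # the spectral sub-pipeline commutes with orthogonal conjugation
        x = rng.normal(size=(5, 7, 7))
        P = weighted_covariance(normalize_features(x, CFG)).entries.data
        R, _ = np.linalg.qr(rng.normal(size=(5, 5)))

        def tail(Pmat):
            st = regularize_and_decompose(Pmat, CFG)
            lam_en = enhance_eigenvalues(st.lambdas_reg)
            _, _, s_f = dynamic_scaling(st.U, lam_en)
            U, le = st.U.data, lam_en.data
            A = (s_f.item() + 1.0) * (U * np.sqrt(le)) @ U.T
            return A, s_f.item()

        A1, s1 = tail(P)
        A2, s2 = tail(R @ P @ R.T)
        assert abs(s1 - s2) < 1e-6
        np.testing.assert_allclose(A2, R @ A1 @ R.T, atol=1e-6)

    def test_batched_matches_per_sample(self, rng):
        xb = rng.normal(size=(3, 4, 5, 5))
        res_b = egcp_transform(xb, CFG)
        for i in range(3):
            res_i = egcp_transform(xb[i], CFG)
            np.testing.assert_allclose(res_b.a_flat.data[i], res_i.a_flat.data,
                                       atol=1e-10)

    def test_gradient_flows_to_input(self, rng):
        x = Tensor(rng.normal(size=(3, 4, 4)), requires_grad=True)
        res = egcp_transform(x, CFG)
        (res.a_flat ** 2).sum().backward()
        assert x.grad is not None
        assert np.isfinite(x.grad).all()
        assert np.abs(x.grad).max() > 0
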