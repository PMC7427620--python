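import numpy as np
import pytest

import qeegnorm as q
from qeegnorm.headmodel import LeadField
from qeegnorm.inverse import _gcv_curve, _ridge_solve, default_lambda_grid
from qeegnorm.spectra import CrossSpectrum, FrequencyGrid


def make_lf(k, mode="free"):
    n_vox = k.shape[1] // (3 if mode == "free" else 1)
    rng = np.random.default_rng(0)
    vox = rng.uniform(-0.5, 0.5, (n_vox, 3))
    return LeadField(k=k, voxel_xyz=vox, orientation_mode=mode)


def make_cs(s_list, fs=200.0, n=512):
    s = np.asarray(s_list, dtype=complex)
    grid = FrequencyGrid(resolution_hz=fs / n,
                         k=np.arange(1, s.shape[0] + 1), n_fft=n)
    return CrossSpectrum(s=s, grid=grid, n_epochs=10, taper="none",
                         channel_labels=[f"ch{i}" for i in range(s.shape[1])])


class TestRidgeOperator:
    def test_identity_leadfield(self):
        op = q.ridge_inverse_operator(make_lf(np.eye(6)), 0.0)
        assert np.allclose(op.t, np.eye(6))

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(1)
        k = rng.standard_normal((19, 300))
        lam = 0.37
        op = q.ridge_inverse_operator(make_lf(k), lam)
        dense = k.T @ np.linalg.inv(k @ k.T + lam * np.eye(19))
        assert np.allclose(op.t, dense, atol=1e-8)

    def test_operator_residual_identity(self):
        rng = np.random.default_rng(2)
        k = rng.standard_normal((5, 30))
        lam = 1.3
        t = _ridge_solve(k, lam)
        assert np.allclose(t @ (k @ k.T + lam * np.eye(5)), k.T, rtol=1e-9)

    def test_square_invertible_lambda_zero_inverts(self):
        rng = np.random.default_rng(3)
        k = rng.standard_normal((6, 6)) + 3 * np.eye(6)
        t = _ridge_solve(k, 0.0)
        assert np.allclose(t, np.linalg.inv(k), atol=1e-8)

    def test_shrinkage_limit_and_monotone_norm(self):
        rng = np.random.default_rng(4)
        k = rng.standard_normal((4, 12))
        norms = [np.linalg.norm(_ridge_solve(k, lam))
                 for lam in [0.0, 0.1, 1.0, 10.0, 1e6]]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        big = np.linalg.norm(k @ k.T) * 1e12
        assert np.linalg.norm(_ridge_solve(k, big)) < 1e-10

    def test_singular_lambda_zero_raises(self):
        k = np.zeros((3, 9))
        k[0, 0] = 1.0  # rank 1: KK' singular
        with pytest.raises(Exception, match="singular"):
            _ridge_solve(k, 0.0)


class TestGCV:
    def test_two_by_two_hand_value(self):
        """K = diag(1, 2), M = I, lambda = 1: shrinkage residuals are
        1/(1+1)=1/2 and 1/(4+1)=1/5, numerator (1/4 + 1/25)/2 = 0.145,
        denominator ((1/2 + 1/5)/2)^2 = 0.1225, GCV = 1.183673..."""
        k = np.diag([1.0, 2.0])
        curve = _gcv_curve(k, np.eye(2), np.array([1.0]))
        assert curve[0] == pytest.approx(0.145 / 0.1225, rel=1e-12)

    def test_gcv_matches_dense_definition(self):
        rng = np.random.default_rng(5)
        k = rng.standard_normal((6, 20))
        x = rng.standard_normal((6, 40))
        m = x @ x.T
        lambdas = np.geomspace(0.01, 100, 7)
        curve = _gcv_curve(k, m, lambdas)
        n = 6
        for lam, got in zip(lambdas, curve):
            h = k @ k.T @ np.linalg.inv(k @ k.T + lam * np.eye(n))
            r = np.eye(n) - h
            expect = (np.trace(r @ m @ r.T) / n) / (np.trace(r) / n) ** 2
            assert got == pytest.approx(expect, rel=1e-9)

    def test_noiseless_data_selects_smallest_lambda(self):
        rng = np.random.default_rng(6)
        k = rng.standard_normal((8, 24))
        j = rng.standard_normal((24, 30))
        x = k @ j  # exactly representable data
        s = (x @ x.T)[None, :, :].astype(complex)
        lf = make_lf(k)
        lambdas = np.geomspace(1e-6, 1e2, 9)
        assert q.select_lambda_gcv(lf, make_cs(s), lambdas) == lambdas[0]

    def test_pure_noise_prefers_heavy_regularization(self):
        rng = np.random.default_rng(7)
        k = rng.standard_normal((8, 24)) * 1e-6  # negligible gain
        x = rng.standard_normal((8, 200))
        s = (x @ x.T)[None, :, :].astype(complex)
        lambdas = np.geomspace(1e-16, 1e-4, 13)
        chosen = q.select_lambda_gcv(make_lf(k), make_cs(s), lambdas)
        assert chosen >= lambdas[len(lambdas) // 2]

    def test_too_few_candidates(self, leadfield19):
        s = np.eye(19)[None, :, :].astype(complex)
        with pytest.raises(ValueError, match="3 candidate"):
            q.select_lambda_gcv(leadfield19, make_cs(s), np.array([1.0, 2.0]))

    def test_zero_data_error(self, leadfield19):
        s = np.zeros((2, 19, 19), dtype=complex)
        with pytest.raises(ValueError, match="zero cross-spectrum"):
            q.select_lambda_gcv(leadfield19, make_cs(s),
                                np.array([0.1, 1.0, 10.0]))


class TestSourceSpectra:
    def test_identity_transport(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((6, 6))
        s = (a @ a.T)[None, :, :].astype(complex)
        op = q.ridge_inverse_operator(make_lf(np.eye(6)), 0.0)
        ss = q.source_spectra(op, make_cs(s), n_components=3)
        grouped = np.diag(s[0].real).reshape(2, 3).sum(axis=1)
        assert np.allclose(ss.power[:, 0], grouped)

    def test_zero_cross_spectrum(self):
        op = q.ridge_inverse_operator(make_lf(np.eye(6)), 0.1)
        ss = q.source_spectra(op, make_cs(np.zeros((3, 6, 6))), n_components=3)
        assert np.array_equal(ss.power, np.zeros((2, 3)))

    def test_matches_dense_diagonal_oracle(self):
        rng = np.random.default_rng(9)
        k = rng.standard_normal((5, 12))
        a = rng.standard_normal((5, 5)) + 1j * rng.standard_normal((5, 5))
        s = (a @ np.conj(a.T))[None, :, :]
        op = q.ridge_inverse_operator(make_lf(k), 0.5)
        ss = q.source_spectra(op, make_cs(s), n_components=3)
        dense = np.real(np.diag(op.t @ s[0] @ np.conj(op.t.T)))
        assert np.allclose(ss.power[:, 0], dense.reshape(4, 3).sum(axis=1),
                           rtol=1e-9)

    def test_nonnegative_for_psd_input(self):
        rng = np.random.default_rng(10)
        k = rng.standard_normal((7, 21))
        mats = []
        for _ in range(4):
            a = rng.standard_normal((7, 7)) + 1j * rng.standard_normal((7, 7))
            mats.append(a @ np.conj(a.T))
        op = q.ridge_inverse_operator(make_lf(k), 0.01)
        ss = q.source_spectra(op, make_cs(mats), n_components=3)
        assert ss.power.min() >= 0.0

    def test_total_power_monotone_in_lambda(self):
        rng = np.random.default_rng(11)
        k = rng.standard_normal((6, 18))
        a = rng.standard_normal((6, 6))
        s = (a @ a.T)[None, :, :].astype(complex)
        lf = make_lf(k)
        totals = []
        for lam in [1e-3, 1e-2, 1e-1, 1.0, 10.0]:
            op = q.ridge_inverse_operator(lf, lam)
            totals.append(q.source_spectra(op, make_cs(s),
                                           n_components=3).power.sum())
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestRidgeInverseEstimator:
    def test_sklearn_params_roundtrip(self):
        est = q.RidgeInverse(lam=0.5, normalize_depth=False)
        assert est.get_params()["lam"] == 0.5
        est.set_params(lam="gcv")
        assert est.lam == "gcv"

    def test_depth_normalization_undone_on_output(self):
        """Round-trip through a square invertible gain is exact at lambda=0
        whether or not depth weighting is enabled."""
        rng = np.random.default_rng(12)
        k = rng.standard_normal((6, 6)) + 3 * np.eye(6)
        lf = make_lf(k)
        a = rng.standard_normal((6, 6))
        cs = make_cs((a @ a.T)[None, :, :])
        for normalize in (False, True):
            est = q.RidgeInverse(lam=0.0, normalize_depth=normalize).fit(lf)
            assert np.allclose(est.t_ @ k, np.eye(6), atol=1e-8)
            ss = est.transform(cs)
            assert ss.power.shape == (2, 1)

    def test_per_bin_mode_matches_global_on_single_bin(self):
        rng = np.random.default_rng(13)
        k = rng.standard_normal((5, 15))
        a = rng.standard_normal((5, 5))
        cs = make_cs((a @ a.T)[None, :, :])
        lf = make_lf(k)
        glob = q.RidgeInverse(lam=0.3).fit(lf, cs).transform(cs)
        per = q.RidgeInverse(lam=0.3, per_bin=True).fit(lf, cs).transform(cs)
        assert np.allclose(glob.power, per.power, rtol=1e-9)
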