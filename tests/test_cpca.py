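"""Complex PCA: analytic signal, Hermitian correlation, eigenpairs,
phase conventions and pattern reconstruction."""

import numpy as np
import pytest

from spatiodyn import (ICNTimeSeries, analytic_signal, canonical_phase,
                       complex_corr, cpca, decompose, make_traveling_wave,
                       reconstruct_pattern)


def fft_analytic_oracle(x: np.ndarray) -> np.ndarray:
    """Frequency-domain construction: zero negative frequencies, double
    positive ones (independent of scipy.signal.hilbert)."""
    n = len(x)
    X = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1:n // 2] = 2.0
    else:
        h[1:(n + 1) // 2] = 2.0
    return np.fft.ifft(X * h)


def power_iteration_eigh(R: np.ndarray, iters: int = 10_000):
    """Brute-force leading-eigenpair oracle with deflation (N <= 4)."""
    R = R.astype(complex)
    vals, vecs = [], []
    M = R.copy()
    rng = np.random.default_rng(0)
    for _ in range(R.shape[0]):
        v = rng.standard_normal(R.shape[0]) + 1j * rng.standard_normal(R.shape[0])
        v /= np.linalg.norm(v)
        for _ in range(iters):
            v = M @ v
            n = np.linalg.norm(v)
            if n == 0:
                break
            v /= n
        lam = float(np.real(v.conj() @ M @ v))
        vals.append(lam)
        vecs.append(v)
        M = M - lam * np.outer(v, v.conj())
    return np.array(vals), np.column_stack(vecs)


class TestAnalyticSignal:
    def test_sinusoid_has_unit_envelope(self):
        t = np.arange(2000) * 1.0
        x = np.cos(2 * np.pi * 0.05 * t)
        ts = ICNTimeSeries(np.column_stack([x, x]), 1.0)
        Z = analytic_signal(ts).Z
        assert np.abs(np.abs(Z[100:-100, 0]) - 1.0).max() < 0.05

    def test_zero_input_gives_zero(self):
        Z = analytic_signal(ICNTimeSeries(np.zeros((64, 2)), 1.0)).Z
        np.testing.assert_array_equal(Z, 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_fft_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((128, 3))
        x -= x.mean(axis=0)
        Z = analytic_signal(ICNTimeSeries(x, 1.0)).Z
        for j in range(3):
            np.testing.assert_allclose(Z[:, j], fft_analytic_oracle(x[:, j]),
                                       atol=1e-10)

    def test_real_part_equals_input(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((100, 4))
        x -= x.mean(axis=0)
        Z = analytic_signal(ICNTimeSeries(x, 1.0)).Z
        np.testing.assert_allclose(Z.real, x, atol=1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            analytic_signal(ICNTimeSeries(np.ones((3, 2)), 1.0))


class TestComplexCorr:
    def test_identical_columns_give_unit_coherence(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(200) + 1j * rng.standard_normal(200)
        R = complex_corr(np.column_stack([z, z]), normalize=True).R
        assert R[0, 1] == pytest.approx(1.0 + 0.0j, abs=1e-12)

    def test_quadrature_pair_has_quarter_cycle_phase(self):
        t = np.arange(4000) * 1.0
        w = 2 * np.pi * 0.05
        x = np.column_stack([np.cos(w * t), np.sin(w * t)])
        Z = analytic_signal(ICNTimeSeries(x, 1.0)).Z
        R = complex_corr(Z, normalize=True, edge_exclude=100).R
        assert abs(np.angle(R[0, 1]) - np.pi / 2) < 0.05

    def test_hermitian_symmetry(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((150, 6)) + 1j * rng.standard_normal((150, 6))
        R = complex_corr(Z, normalize=False).R
        assert np.abs(R - R.conj().T).max() < 1e-12

    def test_zero_power_column_rejected_when_normalizing(self):
        Z = np.column_stack([np.ones(50) + 1j, np.zeros(50)]).astype(complex)
        Z[:, 0] -= Z[:, 0].mean()
        Z[:, 0] += np.exp(1j * np.arange(50))
        with pytest.raises(ValueError, match="2"):
            complex_corr(Z, normalize=True)


class TestDecompose:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(2)
        u = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        u /= np.linalg.norm(u)
        t = np.arange(3000)
        s = np.exp(1j * 2 * np.pi * 0.03 * t)
        Z = np.outer(s, u)
        R = complex_corr(Z, normalize=False)
        res = decompose(R, Z, n_components=1)
        assert abs(res.loadings[:, 0].conj() @ u) >= 0.999

    def test_traveling_wave_phase_gradient(self):
        ts = make_traveling_wave(16, 512, 1.0, 0.05, np.pi / 8, noise_sd=0.0)
        res = cpca(ts, edge_exclude=32)
        phase = np.unwrap(res.phase_map)
        m = np.arange(16)
        slope = np.polyfit(m, phase, 1)[0]
        assert slope == pytest.approx(-np.pi / 8, abs=0.01)
        r = np.corrcoef(phase, -m * np.pi / 8)[0, 1]
        assert r >= 0.99

    def test_phase_recovery_rms_error(self):
        ts = make_traveling_wave(16, 512, 1.0, 0.05, np.pi / 8, noise_sd=0.0)
        res = cpca(ts, edge_exclude=32)
        phase = np.unwrap(res.phase_map)
        m = np.arange(16)
        target = -m * np.pi / 8
        resid = (phase - phase.mean()) - (target - target.mean())
        assert np.sqrt(np.mean(resid ** 2)) < 0.01

    def test_isotropic_matrix_has_equal_eigenvalues(self):
        res = decompose(np.eye(5, dtype=complex), None, n_components=5)
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=1e-6)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_eigenpairs_match_power_iteration_oracle(self, n):
        rng = np.random.default_rng(n)
        A = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        R = A @ A.conj().T / n
        res = decompose(R, None, n_components=n)
        vals, vecs = power_iteration_eigh(R)
        np.testing.assert_allclose(res.eigenvalues, vals, atol=1e-6)
        for k in range(n):
            assert abs(res.loadings[:, k].conj() @ vecs[:, k]) >= 0.999

    def test_eigenvalue_sum_equals_trace(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((300, 7)) + 1j * rng.standard_normal((300, 7))
        R = complex_corr(Z, normalize=True)
        res = decompose(R, Z, n_components=7)
        assert res.eigenvalues.sum() == pytest.approx(
            float(np.real(np.trace(R.R))), rel=1e-9)

    def test_amplitude_map_gauge_invariant(self):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal((200, 5)) + 1j * rng.standard_normal((200, 5))
        a = decompose(complex_corr(Z), Z).amplitude_map
        Zr = Z * np.exp(1j * 0.83)
        b = decompose(complex_corr(Zr), Zr).amplitude_map
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestCanonicalPhase:
    def test_already_canonical_is_fixed_point(self):
        u = np.array([1.0, 0.5, 0.25], dtype=complex)
        np.testing.assert_allclose(canonical_phase(u), u, atol=1e-12)

    def test_gauge_invariance(self):
        rng = np.random.default_rng(7)
        u = rng.standard_normal(5) + 1j * rng.standard_normal(5)
        a = canonical_phase(u * np.exp(1j * 1.3))
        b = canonical_phase(u)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_three_element_hand_computation(self):
        u = np.array([2.0 * np.exp(1j * 0.4), 1.0 * np.exp(-1j * 0.2),
                      0.5 * np.exp(1j * 1.0)])
        # amplitude-weighted circular mean: arg(sum |u| e^{i arg u}) = arg(sum u)
        phi = np.angle(np.sum(u))
        np.testing.assert_allclose(canonical_phase(u), u * np.exp(-1j * phi),
                                   atol=1e-12)
        # weighted mean phase of the result is zero
        out = canonical_phase(u)
        assert abs(np.angle(np.sum(out))) < 1e-9

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            canonical_phase(np.zeros(3, dtype=complex))


class TestReconstructPattern:
    def test_real_positive_loading_peaks_at_frame_zero(self):
        u = np.array([1.0, 0.5], dtype=complex)
        pat = reconstruct_pattern(u, 8)
        assert np.argmax(pat[0]) == 0
        np.testing.assert_allclose(pat[0], np.cos(2 * np.pi * np.arange(8) / 8),
                                   atol=1e-12)

    def test_quarter_phase_loading_peaks_quarter_cycle_earlier(self):
        u = np.array([1.0, np.exp(1j * np.pi / 2)])
        pat = reconstruct_pattern(u, 8)
        assert np.argmax(pat[1]) == (np.argmax(pat[0]) - 2) % 8

    def test_rank_one_cycle_recovered_end_to_end(self):
        # forward-time rank-1 data x(t) = Re(u e^{i w t}); the planted
        # cycle is the data's own first period, and the leading
        # component's reconstruction matches it up to circular shift
        rng = np.random.default_rng(8)
        u = canonical_phase(rng.standard_normal(10)
                            + 1j * rng.standard_normal(10))
        u /= np.linalg.norm(u)
        W = 8
        t = np.arange(4096)
        x = np.real(np.outer(np.exp(1j * 2 * np.pi * t / W), u))
        planted = x[:W].T  # N x W, one full cycle
        # unnormalized R keeps the amplitude profile of the loadings
        res = cpca(ICNTimeSeries(x, 1.0), normalize=False, edge_exclude=32)
        rec = reconstruct_pattern(res.loadings[:, 0], W)
        corrs = [np.corrcoef(np.roll(rec, s, axis=1).ravel(), planted.ravel())[0, 1]
                 for s in range(W)]
        assert max(abs(c) for c in corrs) >= 0.95
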