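import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qeegnorm as q

from conftest import random_epochs


def dft_oracle(e, grid, taper="none"):
    """Brute-force O(N^2) DFT-sum cross-spectrum, independent of the FFT path."""
    n = e.n_samples
    w = np.ones(n) if taper == "none" else np.hanning(n)
    u = np.mean(w ** 2)
    s = np.zeros((grid.n_bins, e.n_channels, e.n_channels), dtype=complex)
    for ep in range(e.n_epochs):
        x = e.data[ep] - e.data[ep].mean(axis=0, keepdims=True)
        x = x * w[:, None]
        for ki, k in enumerate(grid.k):
            v = np.zeros(e.n_channels, dtype=complex)
            for t in range(n):
                v += x[t] * np.exp(-2j * np.pi * k * t / n)
            scale = (1.0 if k == n // 2 else 2.0) / (n * n * u)
            s[ki] += scale * np.outer(v, np.conj(v))
    return s / e.n_epochs


class TestFrequencyGrid:
    def test_canonical_resolution(self, grid_200_512):
        """2.56 s epochs sampled every 5 ms give 0.390625 Hz, shown as 0.39."""
        assert grid_200_512.resolution_hz == pytest.approx(0.390625)
        assert grid_200_512.display_resolution_hz == 0.39

    def test_simple_resolution(self):
        assert q.build_frequency_grid(256, 128, 19.5).resolution_hz == 0.5

    def test_bin_count_and_top_bin(self, grid_200_512):
        # brute-force enumeration of multiples of the resolution below fmax
        expected = [k * 0.390625 for k in range(1, 1000)
                    if k * 0.390625 < 19.5]
        assert grid_200_512.n_bins == len(expected) == 49
        assert grid_200_512.bin_hz[-1] == pytest.approx(19.140625)
        assert grid_200_512.display_labels_hz[-1] == 19.11

    def test_dc_excluded(self, grid_200_512):
        assert grid_200_512.k[0] == 1

    def test_full_grid_includes_nyquist(self):
        g = q.build_frequency_grid(64, 64.0, 32.0)
        assert g.k[-1] == 32

    def test_fmax_below_first_bin(self):
        with pytest.raises(ValueError, match="below the first bin"):
            q.build_frequency_grid(64, 64.0, 0.5)


class TestCrossSpectrum:
    def test_sinusoid_power_identity(self):
        fs, n, k0, amp = 200.0, 512, 26, 3.0
        t = np.arange(n) / fs
        x = amp * np.sin(2 * np.pi * (k0 * fs / n) * t)
        e = q.EpochSet(x[None, :, None], fs, ["Cz"])
        grid = q.build_frequency_grid(n, fs, 19.5)
        s = q.cross_spectrum(e, grid).s[:, 0, 0].real
        assert s[k0 - 1] == pytest.approx(amp ** 2 / 2, rel=1e-9)
        off = np.delete(s, k0 - 1)
        assert np.abs(off).max() <= 1e-9 * amp ** 2

    def test_duplicate_channels(self, grid_200_512):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 512, 1))
        e = q.EpochSet(np.concatenate([x, x], axis=2), 200.0, ["a", "b"])
        s = q.cross_spectrum(e, grid_200_512).s
        assert np.allclose(s[:, 0, 1], s[:, 0, 0])
        assert np.abs(s[:, 0, 1].imag).max() < 1e-12

    @pytest.mark.parametrize("taper", ["none", "hann"])
    def test_matches_dft_oracle(self, taper):
        e = random_epochs(11, n_epochs=2, n_samples=16, n_channels=2, fs=16.0)
        grid = q.build_frequency_grid(16, 16.0, 7.0)
        fast = q.cross_spectrum(e, grid, taper=taper).s
        slow = dft_oracle(e, grid, taper=taper)
        assert np.allclose(fast, slow, rtol=1e-9, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_channels=st.integers(1, 3),
           n_epochs=st.integers(1, 3))
    def test_oracle_property(self, seed, n_channels, n_epochs):
        e = random_epochs(seed, n_epochs=n_epochs, n_samples=8,
                          n_channels=n_channels, fs=8.0)
        grid = q.build_frequency_grid(8, 8.0, 4.0)
        assert np.allclose(q.cross_spectrum(e, grid).s, dft_oracle(e, grid),
                           rtol=1e-9, atol=1e-12)

    def test_parseval(self):
        """One-sided power (Nyquist un-doubled) sums to the mean variance."""
        e = random_epochs(5, n_epochs=4, n_samples=256, n_channels=3, fs=128.0)
        grid = q.build_frequency_grid(256, 128.0, 64.0)
        power = q.narrowband_power(q.cross_spectrum(e, grid)).power
        x = e.data - e.data.mean(axis=1, keepdims=True)
        var = (x ** 2).mean(axis=(0, 1))
        assert np.allclose(power.sum(axis=1), var, rtol=1e-6)

    def test_hermitian_and_psd(self):
        e = random_epochs(6, n_epochs=3, n_samples=64, n_channels=4, fs=64.0)
        grid = q.build_frequency_grid(64, 64.0, 30.0)
        s = q.cross_spectrum(e, grid).s
        assert np.allclose(s, np.conj(np.transpose(s, (0, 2, 1))))
        for k in range(s.shape[0]):
            eig = np.linalg.eigvalsh(s[k])
            assert eig.min() >= -1e-9 * np.trace(s[k]).real

    def test_grid_mismatch_error(self, grid_200_512):
        e = random_epochs(7, n_samples=64, fs=64.0)
        with pytest.raises(ValueError, match="grid"):
            q.cross_spectrum(e, grid_200_512)


class TestNarrowband:
    def test_zero_signal(self, grid_200_512):
        e = q.EpochSet(np.zeros((1, 512, 2)), 200.0, ["a", "b"])
        nb = q.narrowband_power(q.cross_spectrum(e, grid_200_512))
        assert np.array_equal(nb.power, np.zeros((2, 49)))

    def test_matches_oracle_periodogram(self):
        e = random_epochs(8, n_epochs=3, n_samples=16, n_channels=2, fs=16.0)
        grid = q.build_frequency_grid(16, 16.0, 7.0)
        nb = q.narrowband_power(q.cross_spectrum(e, grid))
        oracle = np.einsum("kcc->ck", dft_oracle(e, grid)).real
        assert np.allclose(nb.power, oracle, rtol=1e-9)


class TestCoherencePhase:
    def test_identical_channels(self, grid_200_512):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 512, 1))
        e = q.EpochSet(np.concatenate([x, x], axis=2), 200.0, ["a", "b"])
        cp = q.coherence_phase(q.cross_spectrum(e, grid_200_512))
        assert np.allclose(cp.coh[:, 0, 1], 1.0)
        assert np.allclose(cp.phase[:, 0, 1], 0.0, atol=1e-9)

    def test_quarter_period_delay_phase(self):
        fs, n, k0 = 200.0, 512, 16
        f = k0 * fs / n  # 6.25 Hz; quarter period = n/(4 k0) = 8 samples
        t = np.arange(n) / fs
        delay = int(n / (4 * k0))
        rng = np.random.default_rng(2)
        epochs = []
        for _ in range(4):
            phase = rng.uniform(0, 2 * np.pi)
            x = np.sin(2 * np.pi * f * t + phase)
            epochs.append(np.column_stack([x, np.roll(x, delay)]))
        e = q.EpochSet(np.array(epochs), fs, ["orig", "delayed"])
        grid = q.build_frequency_grid(n, fs, 19.5)
        cp = q.coherence_phase(q.cross_spectrum(e, grid))
        # delayed-vs-original pair lags by a quarter period
        assert cp.phase[k0 - 1, 1, 0] == pytest.approx(-np.pi / 2, abs=0.01)
        assert cp.phase[k0 - 1, 0, 1] == pytest.approx(np.pi / 2, abs=0.01)

    def test_independent_noise_low_coherence(self, grid_200_512):
        rng = np.random.default_rng(3)
        e = q.EpochSet(rng.standard_normal((100, 512, 2)), 200.0, ["a", "b"])
        cp = q.coherence_phase(q.cross_spectrum(e, grid_200_512))
        assert cp.coh[:, 0, 1].mean() < 0.08  # E[coh] ~ 1/E under independence

    def test_single_epoch_coherence_is_one(self, grid_200_512):
        e = random_epochs(9, n_epochs=1, n_samples=512, n_channels=3, fs=200.0)
        cp = q.coherence_phase(q.cross_spectrum(e, grid_200_512))
        iu = np.triu_indices(3, k=1)
        assert np.allclose(cp.coh[:, iu[0], iu[1]], 1.0, atol=1e-9)

    def test_coherence_bounds_and_symmetry(self, grid_200_512):
        e = random_epochs(10, n_epochs=5, n_samples=512, n_channels=4, fs=200.0)
        cp = q.coherence_phase(q.cross_spectrum(e, grid_200_512))
        assert np.nanmin(cp.coh) >= 0.0 and np.nanmax(cp.coh) <= 1.0
        assert np.allclose(cp.coh, np.transpose(cp.coh, (0, 2, 1)))
        assert np.allclose(cp.phase, -np.transpose(cp.phase, (0, 2, 1)))
        idx = np.arange(4)
        assert np.allclose(cp.coh[:, idx, idx], 1.0)
        assert np.allclose(cp.phase[:, idx, idx], 0.0)

    def test_zero_channel_flagged_not_raised(self, grid_200_512):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((2, 512, 2))
        data[..., 1] = 0.0
        e = q.EpochSet(data, 200.0, ["a", "dead"])
        cp = q.coherence_phase(q.cross_spectrum(e, grid_200_512))
        assert not cp.defined[:, 0, 1].any()
        assert np.isnan(cp.coh[:, 0, 1]).all()
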