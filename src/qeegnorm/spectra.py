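"""Frequency-domain estimation: DFT grid, cross-spectra, coherence.

The narrow-band model works on a fine DFT grid whose spacing is set by the
epoch length (2.56 s epochs at 200 Hz give 0.390625 Hz, displayed as
0.39 Hz).  Cross-spectral matrices are Bartlett averages of per-epoch
periodogram outer products, normalized so the one-sided diagonal sums to
the time-domain mean square of the (zero-mean) channel: interior bins
carry the factor 2, the Nyquist bin (only present when the grid extends to
fs/2) is not doubled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import EpochSet


@dataclass
class FrequencyGrid:
    """Positive DFT bins ``k * resolution_hz`` (DC excluded)."""

    resolution_hz: float
    k: np.ndarray  # integer bin indices, increasing, >= 1
    n_fft: int     # epoch length the grid was built for

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        if self.k.size == 0:
            raise ValueError("empty frequency grid")
        if self.k[0] < 1 or np.any(np.diff(self.k) <= 0):
            raise ValueError("bin indices must be increasing and exclude DC")

    @property
    def bin_hz(self) -> np.ndarray:
        """Exact bin frequencies in Hz."""
        return self.k * self.resolution_hz

    @property
    def n_bins(self) -> int:
        return int(self.k.size)

    @property
    def display_resolution_hz(self) -> float:
        """Resolution rounded to 2 decimals for display (0.39 for 0.390625)."""
        return round(self.resolution_hz, 2)

    @property
    def display_labels_hz(self) -> np.ndarray:
        """Bin labels on the rounded spacing, e.g. 0.39, 0.78, ..., 19.11."""
        return np.round(self.k * self.display_resolution_hz, 2)


def build_frequency_grid(n_samples: int, fs: float, fmax_hz: float) -> FrequencyGrid:
    """Build the analysis grid for epochs of ``n_samples`` at ``fs`` Hz.

    Bins are ``k * fs/n_samples`` for ``k = 1 .. floor(fmax/resolution - eps)``,
    strictly below ``fmax_hz``; passing ``fmax_hz = fs/2`` exactly yields the
    full one-sided grid including the (un-doubled) Nyquist bin.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples per epoch")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not (0 < fmax_hz <= fs / 2):
        raise ValueError(f"fmax must lie in (0, fs/2], got {fmax_hz}")
    resolution = fs / n_samples
    if np.isclose(fmax_hz, fs / 2, rtol=0, atol=1e-12):
        k_max = n_samples // 2
    else:
        k_max = int(np.floor(fmax_hz / resolution * (1 - 1e-12)))
    if k_max < 1:
        raise ValueError(f"fmax {fmax_hz} Hz below the first bin {resolution} Hz")
    return FrequencyGrid(resolution_hz=resolution,
                         k=np.arange(1, k_max + 1), n_fft=n_samples)


@dataclass
class CrossSpectrum:
    """Epoch-averaged cross-spectral matrices, microvolt^2 per bin."""

    s: np.ndarray  # complex (bin, channel, channel)
    grid: FrequencyGrid
    n_epochs: int
    taper: str
    channel_labels: Sequence[str] = field(default_factory=list)
    coherence_convention: str = "magnitude-squared"

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=complex)
        if self.s.ndim != 3 or self.s.shape[1] != self.s.shape[2]:
            raise ValueError("s must be (bin, channel, channel)")
        if self.s.shape[0] != self.grid.n_bins:
            raise ValueError("bin axis inconsistent with grid")

    @property
    def n_channels(self) -> int:
        return self.s.shape[1]


@dataclass
class NarrowBandSpectra:
    """Per-channel power on the narrow-band grid (channel, bin)."""

    power: np.ndarray
    grid: FrequencyGrid
    channel_labels: Sequence[str]
    log10: bool = False

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.channel_labels), self.grid.n_bins):
            raise ValueError("power must be (channel, bin) matching labels/grid")
        if not self.log10 and np.any(self.power < 0):
            raise ValueError("raw power must be non-negative")


@dataclass
class CoherencePhase:
    """Magnitude-squared coherence in [0,1] and phase in (-pi, pi]."""

    coh: np.ndarray    # (bin, channel, channel)
    phase: np.ndarray  # (bin, channel, channel), radians
    grid: FrequencyGrid
    channel_labels: Sequence[str]
    defined: np.ndarray = None  # bool (bin, channel, channel)
    convention: str = "magnitude-squared"


def _taper_window(name: str, n: int) -> np.ndarray:
    if name == "none":
        return np.ones(n)
    if name == "hann":
        return np.hanning(n)
    raise ValueError(f"unknown taper {name!r} (use 'none' or 'hann')")


def cross_spectrum(e: EpochSet, grid: FrequencyGrid,
                   taper: str = "none") -> CrossSpectrum:
    """Epoch-averaged cross-spectral matrices on ``grid``.

    Per epoch, the per-channel mean (DC) is removed, the optional taper
    applied, and the DFT outer products averaged:
    ``s[k] = (w_k / E) sum_e V_e(:,k) V_e(:,k)^H`` with
    ``w_k = 2 / (N^2 U)`` at interior bins (``U`` the mean squared taper
    weight) and half that at Nyquist, so the one-sided diagonal sum equals
    the epoch-mean channel variance.
    """
    n = e.n_samples
    if n < 2:
        raise ValueError("epochs must have at least 2 samples")
    if grid.n_fft != n or not np.isclose(grid.resolution_hz, e.fs / n):
        raise ValueError("grid inconsistent with epoch length and sampling rate")
    w = _taper_window(taper, n)
    u = float(np.mean(w ** 2))
    x = e.data - e.data.mean(axis=1, keepdims=True)  # remove per-epoch DC
    v = np.fft.rfft(x * w[None, :, None], axis=1)    # (E, n//2+1, C)
    v = v[:, grid.k, :]                              # (E, K, C)
    # average of outer products over epochs, one matrix per bin
    s = np.einsum("ekc,ekd->kcd", v, np.conj(v)) / e.n_epochs
    weight = np.full(grid.n_bins, 2.0 / (n * n * u))
    weight[grid.k == n // 2] = 1.0 / (n * n * u)     # Nyquist un-doubled
    s *= weight[:, None, None]
    s = 0.5 * (s + np.conj(np.transpose(s, (0, 2, 1))))  # exact Hermitian
    return CrossSpectrum(s=s, grid=grid, n_epochs=e.n_epochs, taper=taper,
                         channel_labels=list(e.channel_labels))


def narrowband_power(cs: CrossSpectrum) -> NarrowBandSpectra:
    """Diagonal of the cross-spectrum: per-channel narrow-band power."""
    diag = np.einsum("kcc->kc", cs.s)
    if np.any(np.abs(diag.imag) > 1e-9 * (np.abs(diag.real) + 1e-30)):
        raise ValueError("cross-spectrum diagonal has non-negligible imaginary part")
    power = np.clip(diag.real.T, 0.0, None)  # (channel, bin)
    return NarrowBandSpectra(power=power, grid=cs.grid,
                             channel_labels=list(cs.channel_labels))


def coherence_phase(cs: CrossSpectrum) -> CoherencePhase:
    """Magnitude-squared coherence and phase differences between all leads.

    Pairs with a zero auto-spectrum at a bin are flagged undefined (NaN in
    the outputs, False in ``defined``) rather than raising.  With a single
    epoch the coherence is identically 1 for every pair.
    """
    s = cs.s
    diag = np.einsum("kcc->kc", s).real  # (K, C)
    denom = diag[:, :, None] * diag[:, None, :]
    defined = denom > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(defined, np.abs(s) ** 2 / np.where(defined, denom, 1.0),
                       np.nan)
    # clip rounding excursions only
    coh = np.where(defined, np.clip(coh, 0.0, 1.0), coh)
    phase = np.angle(s)
    idx = np.arange(cs.n_channels)
    coh[:, idx, idx] = np.where(diag > 0, 1.0, np.nan)
    phase[:, idx, idx] = 0.0
    phase = np.where(defined, phase, np.nan)
    return CoherencePhase(coh=coh, phase=phase, grid=cs.grid,
                          channel_labels=list(cs.channel_labels),
                          defined=defined)
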