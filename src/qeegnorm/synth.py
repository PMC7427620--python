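"""Synthetic data generators: normative cohorts and dipole recordings.

The cohort generator emulates the statistical structure the normative
machinery assumes: per location and frequency bin, log10 power is
Gaussian around a mean that is polynomial in log10(age).  The default
shape is a 1/f-like background whose level declines with age plus a fixed
10 Hz alpha peak whose amplitude grows with log-age — a caricature of
resting eyes-closed EEG, not a simulation of real nonstationarity or
artifacts.  Cohorts can be realized as time-domain epochs by inverse-DFT
spectral shaping with random phases, which makes the per-epoch
periodogram reproduce the drawn spectrum exactly.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .containers import EpochSet, Subject
from .headmodel import LeadField
from .spectra import FrequencyGrid


@dataclass
class CohortSpec:
    """Study conditions for a synthetic normative cohort.

    Defaults mirror the normative-database conditions: 211 subjects,
    ages 5-87 (uniform), between-subject SD 0.2 log10 units.
    """

    n_subjects: int = 211
    age_range: Tuple[float, float] = (5.0, 87.0)
    seed: int = 0
    sigma: float = 0.2               # between-subject SD, log10 power
    bg_offset: float = 1.5           # log10 uV^2 at 1 Hz
    bg_log_slope: float = 1.2        # 1/f-like decline per decade of Hz
    age_slope: float = -0.45         # d(log10 power)/d(log10 age)
    alpha_center_hz: float = 10.0
    alpha_width_hz: float = 1.2
    alpha_amp: float = 0.3           # peak height at u = 0, log10 units
    alpha_amp_age_slope: float = 0.25  # per unit log10(age)

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not (0 < lo < hi <= 120):
            raise ValueError(f"invalid age range {self.age_range}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def mean_log10_power(self, age: float, freqs_hz: np.ndarray) -> np.ndarray:
        """Generator truth: mu(age, f), linear in u = log10(age) per bin."""
        u = np.log10(age)
        f = np.asarray(freqs_hz, dtype=float)
        bg = self.bg_offset - self.bg_log_slope * np.log10(f) + self.age_slope * u
        peak = ((self.alpha_amp + self.alpha_amp_age_slope * u)
                * np.exp(-0.5 * ((f - self.alpha_center_hz)
                                 / self.alpha_width_hz) ** 2))
        return bg + peak


def make_cohort(spec: CohortSpec, grid: FrequencyGrid,
                locations: Sequence[str],
                realize: str = "spectra",
                fs: float = 200.0, n_epochs: int = 24,
                ) -> List[Tuple[np.ndarray | EpochSet, float]]:
    """Draw a cohort: ``[(raw spectra (location, bin) | EpochSet, age), ...]``.

    Spectra are ``10 ** (mu(age, f) + sigma * N(0,1))`` per location and
    bin.  With ``realize="epochs"`` each subject is additionally rendered
    as time-domain epochs whose periodograms equal the drawn spectra.
    """
    if realize not in ("spectra", "epochs"):
        raise ValueError("realize must be 'spectra' or 'epochs'")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, size=spec.n_subjects)
    freqs = grid.bin_hz
    out = []
    for age in ages:
        mu = spec.mean_log10_power(age, freqs)  # (bin,)
        noise = rng.standard_normal((len(locations), grid.n_bins))
        power = 10.0 ** (mu[None, :] + spec.sigma * noise)
        if realize == "spectra":
            out.append((power, float(age)))
        else:
            e = spectra_to_epochs(power, grid, list(locations), fs=fs,
                                  n_epochs=n_epochs, age=float(age), rng=rng)
            out.append((e, float(age)))
    return out


def spectra_to_epochs(power: np.ndarray, grid: FrequencyGrid,
                      labels: Sequence[str], fs: float, n_epochs: int,
                      age: float, rng: np.random.Generator,
                      state: str = "EC") -> EpochSet:
    """Render target per-bin power as epochs via random-phase inverse DFT.

    Coefficients have deterministic magnitude ``N * sqrt(p/2)`` and
    uniform random phase, so every epoch's periodogram equals ``power``
    exactly (no taper, DC removed).
    """
    n = grid.n_fft
    n_ch = power.shape[0]
    amp = n * np.sqrt(power / 2.0)  # (channel, bin)
    data = np.empty((n_epochs, n, n_ch))
    for e in range(n_epochs):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_ch, grid.n_bins))
        coeff = np.zeros((n_ch, n // 2 + 1), dtype=complex)
        coeff[:, grid.k] = amp * np.exp(1j * phases)
        data[e] = np.fft.irfft(coeff, n=n, axis=1).T
    return EpochSet(data=data, fs=fs, channel_labels=list(labels),
                    reference="AVG", subject=Subject(age=age, state=state))


@dataclass
class DipoleSimSpec:
    """A single oscillating dipole recorded through a lead field."""

    voxel: int
    freq_hz: float
    snr_db: float = 20.0
    orientation: Sequence[float] | str = "radial"
    n_epochs: int = 50
    epoch_s: float = 2.56
    fs: float = 200.0
    amplitude: float = 1.0  # dipole moment amplitude
    seed: int = 0


def simulate_dipole_epochs(spec: DipoleSimSpec, lf: LeadField) -> EpochSet:
    """Scalp epochs of one sinusoidal dipole plus white sensor noise.

    The oscillation frequency must fall on a DFT bin of the epoch.  Noise
    is scaled so the channel-mean signal-to-noise power ratio *at the
    oscillation bin* equals ``snr_db``.  Each epoch gets an independent
    random phase.
    """
    n = int(round(spec.epoch_s * spec.fs))
    k0 = spec.freq_hz * n / spec.fs
    if abs(k0 - round(k0)) > 1e-9 or not (1 <= round(k0) < n / 2):
        raise ValueError(
            f"frequency {spec.freq_hz} Hz is off-grid for {n} samples at "
            f"{spec.fs} Hz")
    if not (0 <= spec.voxel < lf.n_voxels):
        raise ValueError(f"voxel {spec.voxel} outside [0, {lf.n_voxels})")
    block = lf.voxel_block(spec.voxel)  # (channels, components)
    if isinstance(spec.orientation, str):
        if spec.orientation != "radial":
            raise ValueError("orientation must be a 3-vector or 'radial'")
        r0 = lf.voxel_xyz[spec.voxel]
        b = np.linalg.norm(r0)
        q = r0 / b if b > 1e-12 else np.array([0.0, 0.0, 1.0])
    else:
        q = np.asarray(spec.orientation, dtype=float)
        q = q / np.linalg.norm(q)
    gain = block @ q if lf.orientation_mode == "free" else block[:, 0]

    rng = np.random.default_rng(spec.seed)
    t = np.arange(n) / spec.fs
    signal_bin_power = np.mean((gain * spec.amplitude) ** 2) / 2.0
    if np.isfinite(spec.snr_db):
        # white noise of variance v has expected one-sided bin power 2v/n
        noise_var = n * signal_bin_power / (2.0 * 10.0 ** (spec.snr_db / 10.0))
    else:
        noise_var = 0.0
    data = np.empty((spec.n_epochs, n, len(gain)))
    for e in range(spec.n_epochs):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        s = spec.amplitude * np.sin(2.0 * np.pi * spec.freq_hz * t + phase)
        epoch = np.outer(s, gain)
        if noise_var > 0:
            epoch = epoch + rng.normal(0.0, np.sqrt(noise_var),
                                       size=epoch.shape)
        data[e] = epoch
    labels = (list(lf.channel_labels) if lf.channel_labels
              else [f"ch{i}" for i in range(len(gain))])
    return EpochSet(data=data, fs=spec.fs, channel_labels=labels,
                    reference="AVG", subject=Subject(age=30.0))
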