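"""Re-referencing and Global Scale Factor (GSF) correction.

The GSF is a subject-level multiplicative gain on spectral power that
absorbs inter-device and inter-subject amplitude differences unrelated to
neurophysiology (electrode impedance, amplifier gain, skull conductivity).
It is estimated in the log10-power domain as the grand mean deviation of a
subject's transformed spectra from the age-appropriate normative mean, and
divided out before z-scoring, so z-maps reflect spectral *shape* rather
than recording gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet


def rereference(e: EpochSet, target: str) -> EpochSet:
    """Re-reference epochs to a channel, ``"AVG"`` or ``"A1A2"``.

    ``"AVG"`` subtracts the instantaneous mean across channels (every
    sample then has zero channel-mean); a label subtracts that channel's
    signal; ``"A1A2"`` subtracts the mean of channels A1 and A2 (linked
    earlobes).
    """
    data = e.data
    if target == "AVG":
        ref = data.mean(axis=2, keepdims=True)
    elif target == "A1A2":
        ia = e.channel_index("A1")  # raises KeyError if absent
        ib = e.channel_index("A2")
        ref = 0.5 * (data[:, :, ia] + data[:, :, ib])[:, :, None]
    else:
        idx = e.channel_index(target)
        ref = data[:, :, idx][:, :, None]
    return e.copy_with(data=data - ref, reference=target)


@dataclass
class GSF:
    """Global Scale Factor: a positive multiplicative factor on power."""

    log10_value: float

    @property
    def value(self) -> float:
        return float(10.0 ** self.log10_value)


def estimate_gsf(y: np.ndarray, mu: np.ndarray) -> GSF:
    """Estimate the GSF from transformed spectra against normative means.

    Parameters
    ----------
    y : ndarray (location, bin)
        Subject's log10-power spectra.
    mu : ndarray (location, bin)
        Normative mean log10-power at the subject's age.

    The estimator is the arithmetic mean of ``y - mu`` over all locations
    and bins — the maximum-likelihood gain under an i.i.d. Gaussian
    log-residual model — so after :func:`apply_gsf` the residual grand
    mean is exactly zero.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs mu {mu.shape}")
    if y.size == 0:
        raise ValueError("empty spectra")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(mu))):
        raise ValueError("non-finite input")
    return GSF(log10_value=float(np.mean(y - mu)))


def apply_gsf(y: np.ndarray, g: GSF) -> np.ndarray:
    """Remove the GSF from log10-power spectra (``y - log10_value``)."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input")
    return y - g.log10_value
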