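"""Broad Band Model: Absolute Power, Relative Power, Mean Frequency.

Bands are resolved against the displayed (rounded) bin labels with closed
intervals ``low <= f <= high``; the default Delta/Theta/Alpha/Beta edges
are exact first/last bin labels on the 0.39 Hz grid, so the four bands
partition bins 4..49 and nothing is double-counted.  AP and MF are
computed for every band including Total; RP excludes Total (it is the
fraction of Total power, so it sums to 1 across the four bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .spectra import NarrowBandSpectra

#: Classical qEEG band edges on the 0.39 Hz displayed grid (inclusive).
DEFAULT_BANDS: Dict[str, Tuple[float, float]] = {
    "Delta": (1.56, 3.51),
    "Theta": (3.90, 7.41),
    "Alpha": (7.80, 12.48),
    "Beta": (12.87, 19.14),
}

TOTAL = "Total"


@dataclass
class BandSet:
    """Named frequency intervals resolved to bin index sets on a grid."""

    edges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        if TOTAL in self.edges:
            raise ValueError("'Total' is derived, not a configurable band")
        for name, (low, high) in self.edges.items():
            if not (low < high):
                raise ValueError(f"band {name!r}: need low < high")

    @property
    def names(self) -> List[str]:
        return list(self.edges)

    def bin_indices(self, nb_labels: np.ndarray) -> Dict[str, np.ndarray]:
        """Map band name -> bin index array (on displayed labels, inclusive).

        ``Total`` gets every bin that falls in any band.
        """
        out: Dict[str, np.ndarray] = {}
        union = np.zeros(nb_labels.shape[0], dtype=bool)
        for name, (low, high) in self.edges.items():
            mask = (nb_labels >= low - 1e-9) & (nb_labels <= high + 1e-9)
            if not mask.any():
                raise ValueError(f"band {name!r} [{low}, {high}] contains no bins")
            out[name] = np.flatnonzero(mask)
            union |= mask
        out[TOTAL] = np.flatnonzero(union)
        return out


@dataclass
class BroadBandParams:
    """AP (uV^2), RP (fraction) and MF (Hz) per band x channel."""

    bands: List[str]            # includes Total last
    channel_labels: Sequence[str]
    ap: np.ndarray              # (band, channel), incl. Total
    rp: np.ndarray              # (band-1, channel), excl. Total
    mf: np.ndarray              # (band, channel), incl. Total
    mf_degenerate: np.ndarray   # bool (band, channel): zero-power band


def broadband_params(nb: NarrowBandSpectra, bands: BandSet | None = None
                     ) -> BroadBandParams:
    """Integrate narrow-band spectra into the broad-band parameters.

    ``ap_b(c) = sum_k power[c,k]``; ``rp_b = ap_b / ap_Total``;
    ``mf_b = sum f_k p[c,k] / sum p[c,k]`` (band midpoint, flagged, when
    the band power is zero).
    """
    if nb.log10:
        raise ValueError("broadband_params needs raw (non-log) spectra")
    bands = bands if bands is not None else BandSet()
    labels = nb.grid.display_labels_hz
    freqs = nb.grid.bin_hz
    idx = bands.bin_indices(labels)
    names = bands.names + [TOTAL]
    n_ch = nb.power.shape[0]
    ap = np.zeros((len(names), n_ch))
    mf = np.zeros((len(names), n_ch))
    degenerate = np.zeros((len(names), n_ch), dtype=bool)
    for b, name in enumerate(names):
        k = idx[name]
        p = nb.power[:, k]  # (channel, bins-in-band)
        ap[b] = p.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mf[b] = (p * freqs[k]).sum(axis=1) / ap[b]
        zero = ap[b] <= 0
        mf[b, zero] = 0.5 * (freqs[k[0]] + freqs[k[-1]])
        degenerate[b, zero] = True
    total = ap[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        rp = np.where(total > 0, ap[:-1] / np.where(total > 0, total, 1.0), 0.0)
    return BroadBandParams(bands=names, channel_labels=list(nb.channel_labels),
                           ap=ap, rp=rp, mf=mf, mf_degenerate=degenerate)
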