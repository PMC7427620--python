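"""Core in-memory containers shared across the pipeline.

An :class:`EpochSet` holds expert-selected, artifact-free EEG epochs as a
dense ``(epoch, sample, channel)`` array in microvolts, together with the
sampling rate, channel labels, reference descriptor and subject metadata.
A :class:`Montage` holds labeled electrode positions on the unit sphere
(head radius normalized to 1, +z through the vertex).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

VALID_STATES = ("EC", "EO", "HV")


@dataclass
class Subject:
    """Recording-level metadata: age in years, state (EC/EO/HV), id."""

    age: float
    state: str = "EC"
    id: str = ""

    def __post_init__(self) -> None:
        if not (0 < float(self.age) <= 200):
            raise ValueError(f"age must be a positive number of years, got {self.age}")
        if self.state not in VALID_STATES:
            raise ValueError(f"state must be one of {VALID_STATES}, got {self.state!r}")


@dataclass
class EpochSet:
    """Epoched multichannel EEG, microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_epochs, n_samples, n_channels)
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique, order-preserving channel labels.
    reference : str
        A channel label, ``"AVG"`` (average reference) or ``"A1A2"``
        (linked earlobes).
    subject : Subject
    """

    data: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    reference: str = "AVG"
    subject: Subject = field(default_factory=lambda: Subject(age=30.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (epoch, sample, channel), got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[2]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[2]} channels"
            )
        lower = [c.lower() for c in self.channel_labels]
        if len(set(lower)) != len(lower):
            raise ValueError("channel labels must be unique (case-insensitive)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EpochSet data contains non-finite samples")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        """Index of a channel by case-insensitive label."""
        lower = [c.lower() for c in self.channel_labels]
        try:
            return lower.index(label.lower())
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage {self.channel_labels}")

    def copy_with(self, **kwargs) -> "EpochSet":
        return replace(self, **kwargs)


@dataclass
class Montage:
    """Labeled electrode positions on the unit sphere."""

    labels: Sequence[str]
    positions: np.ndarray  # (n, 3), unit norm

    def __post_init__(self) -> None:
        self.labels = [str(c) for c in self.labels]
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        lower = [c.lower() for c in self.labels]
        if len(set(lower)) != len(lower):
            raise ValueError("montage labels must be unique")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("montage positions must lie on the unit sphere")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, labels: Sequence[str]) -> "Montage":
        lower = {c.lower(): i for i, c in enumerate(self.labels)}
        idx = [lower[c.lower()] for c in labels]
        return Montage([self.labels[i] for i in idx], self.positions[idx])
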