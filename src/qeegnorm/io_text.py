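"""Plain-text interchange formats.

Three formats are defined here and used throughout:

* the epoch text format (``QEEGT-TEXT 1``) carrying epoched EEG in
  microvolts with sampling and subject metadata,
* montage tables (``label x y z`` per line, unit-sphere positions),
* the versioned norms container (``qeegnorm-v1``): JSON metadata with
  base64-encoded little-endian float64 coefficient arrays, and
* a lead-field text format (header + row-major gain matrix + voxel table).

All formats are line-oriented ASCII so results diff cleanly and survive
any transport.
"""

from __future__ import annotations

import base64
import json
import warnings
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .containers import EpochSet, Montage, Subject

PathLike = Union[str, Path]

EPOCH_MAGIC = "QEEGT-TEXT 1"
NORMS_VERSION = "qeegnorm-v1"


class FormatError(ValueError):
    """Raised for malformed interchange files; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Epoch text format
# ---------------------------------------------------------------------------

def _parse_header_fields(line: str, lineno: int) -> dict:
    fields = {}
    for token in line.split():
        if "=" not in token:
            raise FormatError(f"malformed header token {token!r}", lineno)
        key, value = token.split("=", 1)
        fields[key] = value
    required = ("fs", "n_epochs", "n_samples", "n_channels", "units",
                "reference", "age", "state")
    missing = [k for k in required if k not in fields]
    if missing:
        raise FormatError(f"header missing field(s) {missing}", lineno)
    if fields["units"] != "uV":
        raise FormatError(
            f"unsupported units {fields['units']!r}; only uV is accepted", lineno)
    return fields


def read_epochs_text(path: PathLike) -> EpochSet:
    """Read the ``QEEGT-TEXT 1`` epoch format into an :class:`EpochSet`.

    Raises :class:`FormatError` (naming the line) on malformed headers,
    dimension mismatches, non-numeric tokens or duplicate channel labels.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != EPOCH_MAGIC:
        raise FormatError(f"expected magic {EPOCH_MAGIC!r}", 1)
    if len(lines) < 3:
        raise FormatError("truncated file: missing header or channel line", len(lines))
    hdr = _parse_header_fields(lines[1], 2)
    try:
        fs = float(hdr["fs"])
        n_epochs = int(hdr["n_epochs"])
        n_samples = int(hdr["n_samples"])
        n_channels = int(hdr["n_channels"])
        age = float(hdr["age"])
    except ValueError as exc:
        raise FormatError(f"non-numeric header value ({exc})", 2)
    labels = lines[2].split()
    if len(labels) != n_channels:
        raise FormatError(
            f"{len(labels)} channel labels, header declares {n_channels}", 3)
    if len({c.lower() for c in labels}) != len(labels):
        raise FormatError("duplicate channel label", 3)

    data = np.empty((n_epochs, n_samples, n_channels), dtype=float)
    lineno = 3
    row_iter = iter(range(3, len(lines)))
    idx = 3
    for e in range(n_epochs):
        got = 0
        while got < n_samples:
            if idx >= len(lines):
                raise FormatError(
                    f"epoch {e}: expected {n_samples} rows, found {got}", len(lines))
            lineno = idx + 1
            line = lines[idx]
            idx += 1
            if not line.strip():
                if got:  # blank line inside a block means the block is short
                    raise FormatError(
                        f"epoch {e}: expected {n_samples} rows, found {got}", lineno)
                continue
            values = line.split()
            if len(values) != n_channels:
                raise FormatError(
                    f"epoch {e} row {got}: {len(values)} values for "
                    f"{n_channels} channels", lineno)
            try:
                data[e, got] = [float(v) for v in values]
            except ValueError:
                raise FormatError(f"non-numeric token in epoch {e}", lineno)
            got += 1
    # anything non-blank after the last block is a dimension mismatch
    for j in range(idx, len(lines)):
        if lines[j].strip():
            raise FormatError("extra data rows beyond declared epochs", j + 1)

    if not np.all(np.isfinite(data)):
        raise FormatError("non-finite sample value", lineno)
    return EpochSet(
        data=data, fs=fs, channel_labels=labels,
        reference=hdr["reference"],
        subject=Subject(age=age, state=hdr["state"]),
    )


def write_epochs_text(e: EpochSet, path: PathLike) -> Path:
    """Write an :class:`EpochSet` in the epoch text format (round-trip safe)."""
    if not np.all(np.isfinite(e.data)):
        raise ValueError("refusing to write EpochSet with non-finite samples")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(EPOCH_MAGIC + "\n")
        fh.write(
            f"fs={e.fs:.10g} n_epochs={e.n_epochs} n_samples={e.n_samples} "
            f"n_channels={e.n_channels} units=uV reference={e.reference} "
            f"age={e.subject.age:.10g} state={e.subject.state}\n"
        )
        fh.write(" ".join(e.channel_labels) + "\n")
        for ep in range(e.n_epochs):
            for row in e.data[ep]:
                fh.write(" ".join(f"{v:.8e}" for v in row) + "\n")
            fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Montages
# ---------------------------------------------------------------------------

# Classical 10-20 positions for the 19-lead montage, as (theta, phi) in
# degrees on the unit sphere: x = sin(theta) cos(phi), y = sin(theta) sin(phi),
# z = cos(theta).  +x through the right pre-auricular point (T4), +y through
# the nasion, +z through the vertex (Cz).
_TEN_TWENTY_19 = {
    "Fp1": (-92, -72), "Fp2": (92, 72),
    "F3": (-60, -51), "F4": (60, 51),
    "C3": (-45, 0), "C4": (45, 0),
    "P3": (-60, 51), "P4": (60, -51),
    "O1": (-92, 72), "O2": (92, -72),
    "F7": (-92, -36), "F8": (92, 36),
    "T3": (-92, 0), "T4": (92, 0),
    "T5": (-92, 36), "T6": (92, -36),
    "Fz": (46, 90), "Cz": (0, 0), "Pz": (46, -90),
}
# The inferior ring (Fp1/2, F7/8, T3/4, T5/6, O1/2) sits 2 deg below the
# equator, as in the classical spherical tables.
TEN_TWENTY_19_LABELS = ["Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
                        "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
                        "Fz", "Cz", "Pz"]


def _ten_twenty_19() -> Montage:
    pos = []
    for label in TEN_TWENTY_19_LABELS:
        theta, phi = np.deg2rad(_TEN_TWENTY_19[label])
        pos.append([np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    np.cos(theta)])
    return Montage(TEN_TWENTY_19_LABELS, np.asarray(pos))


def load_montage(name_or_path: PathLike) -> Montage:
    """Load a montage by built-in name (``"10-20-19"``) or position table.

    Position files have one ``label x y z`` row per electrode.  Positions
    within 10% of unit norm are normalized with a warning; anything further
    off is an error.
    """
    if str(name_or_path) == "10-20-19":
        return _ten_twenty_19()
    path = Path(name_or_path)
    if not path.exists():
        raise FormatError(f"unknown montage name or missing file: {name_or_path}")
    labels, pos = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError("expected 'label x y z'", lineno)
            try:
                xyz = [float(v) for v in parts[1:]]
            except ValueError:
                raise FormatError("non-numeric coordinate", lineno)
            if parts[0].lower() in {c.lower() for c in labels}:
                raise FormatError(f"duplicate label {parts[0]!r}", lineno)
            labels.append(parts[0])
            pos.append(xyz)
    pos = np.asarray(pos, dtype=float)
    norms = np.linalg.norm(pos, axis=1)
    off = np.abs(norms - 1.0)
    if np.any(off > 0.1):
        raise FormatError("montage positions depart >10% from the unit sphere")
    if np.any(off > 1e-9):
        warnings.warn("montage positions normalized onto the unit sphere")
        pos = pos / norms[:, None]
    return Montage(labels, pos)


def write_montage(m: Montage, path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for label, xyz in zip(m.labels, m.positions):
            fh.write(f"{label} {xyz[0]:.12g} {xyz[1]:.12g} {xyz[2]:.12g}\n")
    return path


# ---------------------------------------------------------------------------
# Norms container (qeegnorm-v1)
# ---------------------------------------------------------------------------

def _encode_array(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype="<f8")
    return {"shape": list(a.shape), "dtype": "<f8",
            "data": base64.b64encode(a.tobytes()).decode("ascii")}


def _decode_array(obj: dict) -> np.ndarray:
    raw = base64.b64decode(obj["data"])
    a = np.frombuffer(raw, dtype=obj["dtype"]).copy()
    return a.reshape(obj["shape"])


def write_norms(model, path: PathLike) -> Path:
    """Serialize a fitted :class:`~qeegnorm.norms.NormativeModel`.

    JSON with base64 float64 arrays; lossless (bit-level round-trip).
    """
    from .norms import NormativeModel  # local import avoids cycle
    if not isinstance(model, NormativeModel):
        raise TypeError("write_norms expects a NormativeModel")
    if not hasattr(model, "beta_mu_"):
        raise ValueError("model is not fitted")
    doc = {
        "format": NORMS_VERSION,
        "state": model.state,
        "level": model.level,
        "transform": "log10-power",
        "age_transform": "log10",
        "degree": model.degree,
        "sigma_floor": model.sigma_floor,
        "n_subjects": int(model.n_subjects_),
        "age_range": [float(model.age_range_[0]), float(model.age_range_[1])],
        "locations": list(model.locations_),
        "grid_bin_hz": _encode_array(np.asarray(model.grid_bin_hz_)),
        "beta_mu": _encode_array(model.beta_mu_),
        "beta_sigma": _encode_array(model.beta_sigma_),
        "gsf_two_pass": bool(model.gsf_two_pass_),
    }
    if getattr(model, "residual_z_", None) is not None:
        doc["residual_z"] = _encode_array(model.residual_z_)
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")
    return path


def read_norms(path: PathLike):
    """Read a ``qeegnorm-v1`` norms file back into a fitted model."""
    from .norms import NormativeModel
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"norms file is not valid JSON ({exc})")
    if doc.get("format") != NORMS_VERSION:
        raise FormatError(
            f"norms version mismatch: {doc.get('format')!r} != {NORMS_VERSION!r}")
    model = NormativeModel(degree=doc["degree"], state=doc["state"],
                           level=doc["level"], sigma_floor=doc["sigma_floor"])
    model.beta_mu_ = _decode_array(doc["beta_mu"])
    model.beta_sigma_ = _decode_array(doc["beta_sigma"])
    model.grid_bin_hz_ = _decode_array(doc["grid_bin_hz"])
    model.locations_ = list(doc["locations"])
    model.n_subjects_ = int(doc["n_subjects"])
    model.age_range_ = (float(doc["age_range"][0]), float(doc["age_range"][1]))
    model.gsf_two_pass_ = bool(doc["gsf_two_pass"])
    model.residual_z_ = (_decode_array(doc["residual_z"])
                         if "residual_z" in doc else None)
    n_loc, n_bin = len(model.locations_), model.grid_bin_hz_.shape[0]
    if model.beta_mu_.shape != (n_loc, n_bin, model.degree + 1):
        raise FormatError(
            f"beta_mu shape {model.beta_mu_.shape} inconsistent with "
            f"{n_loc} locations x {n_bin} bins, degree {model.degree}")
    if model.beta_sigma_.shape != model.beta_mu_.shape:
        raise FormatError("beta_sigma shape inconsistent with beta_mu")
    return model


# ---------------------------------------------------------------------------
# Lead field text format
# ---------------------------------------------------------------------------

def write_leadfield(lf, path: PathLike) -> Path:
    from .headmodel import LeadField
    if not isinstance(lf, LeadField):
        raise TypeError("write_leadfield expects a LeadField")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"QEEGT-LEADFIELD 1 nch={lf.k.shape[0]} nvox={lf.n_voxels} "
                 f"mode={lf.orientation_mode} conductivity={lf.conductivity:.10g}\n")
        for row in lf.k:
            fh.write(" ".join(f"{v:.10e}" for v in row) + "\n")
        for xyz in lf.voxel_xyz:
            fh.write(f"{xyz[0]:.12g} {xyz[1]:.12g} {xyz[2]:.12g}\n")
    return path


def read_leadfield(path: PathLike):
    from .headmodel import LeadField
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("QEEGT-LEADFIELD 1"):
        raise FormatError("expected 'QEEGT-LEADFIELD 1' header", 1)
    hdr = _parse_kv(lines[0])
    nch, nvox = int(hdr["nch"]), int(hdr["nvox"])
    mode = hdr["mode"]
    ncols = 3 * nvox if mode == "free" else nvox
    if len(lines) != 1 + nch + nvox:
        raise FormatError(
            f"expected {1 + nch + nvox} lines, found {len(lines)}")
    k = np.array([[float(v) for v in lines[1 + i].split()] for i in range(nch)])
    if k.shape != (nch, ncols):
        raise FormatError(f"gain matrix shape {k.shape}, expected {(nch, ncols)}")
    vox = np.array([[float(v) for v in lines[1 + nch + i].split()]
                    for i in range(nvox)])
    return LeadField(k=k, voxel_xyz=vox, orientation_mode=mode,
                     conductivity=float(hdr.get("conductivity", 0.33)))


def _parse_kv(line: str) -> dict:
    out = {}
    for token in line.split():
        if "=" in token:
            key, value = token.split("=", 1)
            out[key] = value
    return out
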