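"""Analytic spherical-head forward model.

The scalp potential of a current dipole inside a homogeneous conducting
unit sphere (insulating exterior) has the closed form

    V(r) = (1 / 4 pi sigma) q . [ 2 (r - r0) / d^3  +  (r + (r - r0)/d) / F ]

for an electrode at r on the surface (|r| = 1), dipole moment q at r0,
d = |r - r0| and F = 1 - r.r0 + d.  It is the gradient with respect to r0
of the classical monopole surface kernel (2/d - ln F)/(4 pi sigma), and
reduces to V = 3 q.r / (4 pi sigma) for a central dipole.

This is a deliberately simple stand-in head model: source voxels live on a
regular grid inside the 0.85-radius ball of the unit head sphere, and gain
columns are returned average-referenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import Montage

VOXEL_RADIUS = 0.85


@dataclass
class LeadField:
    """Gain matrix: scalp microvolts per unit dipole moment.

    ``k`` has one column per dipole moment component: 3 per voxel in
    ``free`` mode (Cartesian x, y, z), 1 per voxel in ``radial`` mode.
    """

    k: np.ndarray          # (n_channels, n_voxels*3) or (n_channels, n_voxels)
    voxel_xyz: np.ndarray  # (n_voxels, 3), inside the unit sphere
    orientation_mode: str = "free"
    conductivity: float = 0.33
    channel_labels: Sequence[str] = field(default_factory=list)
    grid_spacing: float | None = None

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.voxel_xyz = np.asarray(self.voxel_xyz, dtype=float)
        if self.orientation_mode not in ("free", "radial"):
            raise ValueError("orientation_mode must be 'free' or 'radial'")
        ncomp = 3 if self.orientation_mode == "free" else 1
        if self.k.shape[1] != ncomp * self.voxel_xyz.shape[0]:
            raise ValueError("gain matrix width inconsistent with voxel count")
        if not np.all(np.isfinite(self.k)):
            raise ValueError("non-finite lead field")
        if np.any(np.all(self.k == 0, axis=1)):
            raise ValueError("lead field has an all-zero electrode row")

    @property
    def n_voxels(self) -> int:
        return self.voxel_xyz.shape[0]

    @property
    def n_components(self) -> int:
        return 3 if self.orientation_mode == "free" else 1

    def voxel_block(self, v: int) -> np.ndarray:
        """Gain columns of voxel ``v`` (n_channels, n_components)."""
        c = self.n_components
        return self.k[:, c * v:c * v + c]


def voxel_grid(grid_size: int, radius: float = VOXEL_RADIUS) -> np.ndarray:
    """Regular cubic grid intersected with the ``radius`` ball.

    ``grid_size`` points per axis span ``[-radius, radius]``; grid_size=7
    yields ~180 voxels at spacing ~0.28 head radii.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    axis = np.linspace(-radius, radius, grid_size)
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    keep = np.linalg.norm(pts, axis=1) <= radius + 1e-12
    return pts[keep]


def dipole_potentials(electrodes: np.ndarray, r0: np.ndarray,
                      conductivity: float = 0.33) -> np.ndarray:
    """Gain vectors (n_electrodes, 3) of a dipole at ``r0``, unit sphere.

    Row e is the potential at electrode e per unit moment along x, y, z.
    Potentials are raw (not average-referenced).
    """
    r = np.asarray(electrodes, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    if np.linalg.norm(r0) >= 1.0 - 1e-9:
        raise ValueError("dipole must lie strictly inside the unit sphere")
    diff = r - r0[None, :]                      # (E, 3)
    d = np.linalg.norm(diff, axis=1)            # (E,)
    if np.any(d < 1e-6):
        raise ValueError("dipole coincides with an electrode")
    f = 1.0 - r @ r0 + d                        # (E,)
    g = (2.0 * diff / d[:, None] ** 3
         + (r + diff / d[:, None]) / f[:, None])
    return g / (4.0 * np.pi * conductivity)


def spherical_leadfield(m: Montage, grid_size: int = 7,
                        orientation_mode: str = "free",
                        conductivity: float = 0.33,
                        voxel_xyz: np.ndarray | None = None) -> LeadField:
    """Analytic homogeneous-sphere lead field on a regular voxel grid.

    Columns are the three Cartesian moment components per voxel (``free``)
    or the radial projection (``radial``; the central voxel, where the
    radial direction is undefined, uses +z).  Gains are returned
    average-referenced: each column has zero mean over electrodes.
    """
    if len(m) < 4:
        raise ValueError("need at least 4 electrodes")
    if voxel_xyz is None:
        voxel_xyz = voxel_grid(grid_size)
        spacing = 2 * VOXEL_RADIUS / (grid_size - 1)
    else:
        voxel_xyz = np.asarray(voxel_xyz, dtype=float)
        spacing = None
    if np.any(np.linalg.norm(voxel_xyz, axis=1) > VOXEL_RADIUS + 1e-9):
        raise ValueError(f"voxels must lie within radius {VOXEL_RADIUS}")
    ncomp = 3 if orientation_mode == "free" else 1
    k = np.empty((len(m), ncomp * voxel_xyz.shape[0]))
    for v, r0 in enumerate(voxel_xyz):
        g = dipole_potentials(m.positions, r0, conductivity)  # (E, 3)
        if orientation_mode == "free":
            k[:, 3 * v:3 * v + 3] = g
        else:
            b = np.linalg.norm(r0)
            rad = r0 / b if b > 1e-12 else np.array([0.0, 0.0, 1.0])
            k[:, v] = g @ rad
    k -= k.mean(axis=0, keepdims=True)  # average reference
    return LeadField(k=k, voxel_xyz=voxel_xyz, orientation_mode=orientation_mode,
                     conductivity=conductivity, channel_labels=list(m.labels),
                     grid_spacing=spacing)
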