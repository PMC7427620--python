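"""Ridge-penalty frequency-domain source imaging.

The distributed inverse problem ``y = K j + noise`` is solved per
frequency bin with a ridge penalty: ``j_hat = T y`` with
``T = K' (K K' + lambda I)^{-1}``.  Source power spectra are the
per-voxel diagonal of ``T S(f) T'`` (summed over the three moment
components in free-orientation mode), computed without materializing the
voxel-by-voxel matrix.  The regularization parameter can be fixed or
selected by generalized cross-validation (GCV) on the epoch-stacked
Fourier coefficients over all retained bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .headmodel import LeadField
from .spectra import CrossSpectrum, FrequencyGrid


@dataclass
class InverseOperator:
    """Linear inverse ``t = K' (K K' + lambda I)^{-1}``."""

    t: np.ndarray   # ((voxels * components), channels)
    lam: float
    method: str = "ridge"


@dataclass
class SourceSpectra:
    """Per-voxel power spectra, (dipole moment)^2 per bin."""

    power: np.ndarray      # (voxel, bin)
    grid: FrequencyGrid
    voxel_xyz: np.ndarray
    log10: bool = False


def _ridge_solve(k: np.ndarray, lam: float) -> np.ndarray:
    """Stable ``K'(KK' + lam I)^{-1}`` via Cholesky (or LU at lam=0)."""
    gram = k @ k.T
    n = gram.shape[0]
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    a = gram + lam * np.eye(n)
    if lam == 0:
        # KK' may be singular; let the factorization report it
        try:
            x = linalg.solve(a, k, assume_a="pos")
        except linalg.LinAlgError:
            raise linalg.LinAlgError("KK' is singular; lambda=0 not usable")
    else:
        c, low = linalg.cho_factor(a)
        x = linalg.cho_solve((c, low), k)
    return x.T  # (P, n)


def _gcv_curve(k: np.ndarray, m: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """GCV(lambda) for ridge smoothing of data with second moment ``m``.

    ``m = sum_k Re S(f_k)`` is proportional to ``X X'`` for the stacked
    real/imag Fourier-coefficient matrix X, which is all GCV needs:
    with eigendecomposition ``K K' = Q diag(g) Q'`` and shrinkage residual
    factors ``r_i = lambda / (g_i + lambda)``,
    ``GCV = (sum_i r_i^2 m~_ii / n) / (sum_i r_i / n)^2`` where
    ``m~ = Q' m Q``.
    """
    gram = k @ k.T
    g, q = linalg.eigh(gram)
    g = np.clip(g, 0.0, None)
    mdiag = np.einsum("ij,jk,ki->i", q.T, m, q)  # diagonal of Q' m Q
    n = gram.shape[0]
    out = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        r = lam / (g + lam)
        denom = (r.sum() / n) ** 2
        out[i] = (r ** 2 @ mdiag / n) / denom if denom > 0 else np.inf
    return out


def select_lambda_gcv(lf: LeadField, cs: CrossSpectrum,
                      lambdas: np.ndarray) -> float:
    """Pick the GCV-minimizing ridge parameter (ties -> smaller lambda)."""
    lambdas = np.sort(np.asarray(lambdas, dtype=float))
    if lambdas.size < 3:
        raise ValueError("need at least 3 candidate lambdas")
    if np.any(lambdas <= 0):
        raise ValueError("GCV candidates must be positive")
    m = np.sum(cs.s.real, axis=0)
    if not np.any(m):
        raise ValueError("zero cross-spectrum: GCV is undefined")
    curve = _gcv_curve(lf.k, m, lambdas)
    return float(lambdas[int(np.argmin(curve))])


def default_lambda_grid(k: np.ndarray, n: int = 25) -> np.ndarray:
    """Log-spaced candidates spanning the spectrum of KK'."""
    scale = np.trace(k @ k.T) / k.shape[0]
    return np.geomspace(1e-8 * scale, 1e2 * scale, n)


def ridge_inverse_operator(lf: LeadField, lam: float) -> InverseOperator:
    """The plain ridge operator ``K'(KK' + lambda I)^{-1}`` (no column
    scaling); see :class:`RidgeInverse` for the depth-weighted estimator."""
    return InverseOperator(t=_ridge_solve(lf.k, lam), lam=float(lam))


def source_spectra(op, cs: CrossSpectrum, voxel_xyz=None,
                   n_components: int = 3) -> SourceSpectra:
    """Source power per voxel and bin from an inverse operator.

    ``power[v, f]`` sums, over the voxel's moment components, the diagonal
    of ``T S(f) T'``, extracted as row-wise sums of ``(T S) o conj(T)``.
    """
    t = op.t_ if hasattr(op, "t_") else op.t
    diag = np.einsum("kcc->kc", cs.s).real
    tr = diag.sum(axis=1)
    floor = -1e-6 * (np.abs(tr).max() + 1e-300)
    if np.any(np.einsum("kcc->k", cs.s).real < floor):
        raise ValueError("cross-spectrum is not positive semidefinite")
    a = np.einsum("pc,kcd->kpd", t, cs.s)
    comp_power = np.einsum("kpd,pd->kp", a, np.conj(t)).real  # (bin, P)
    n_vox = t.shape[0] // n_components
    power = comp_power.reshape(cs.grid.n_bins, n_vox, n_components).sum(axis=2)
    power = np.clip(power.T, 0.0, None)  # (voxel, bin); clip rounding only
    if voxel_xyz is None:
        voxel_xyz = getattr(op, "voxel_xyz_", np.zeros((n_vox, 3)))
    return SourceSpectra(power=power, grid=cs.grid, voxel_xyz=voxel_xyz)


class RidgeInverse(BaseEstimator):
    """Ridge source imager with optional depth weighting and GCV.

    Parameters
    ----------
    lam : float or "gcv"
        Ridge penalty; ``"gcv"`` selects it by generalized
        cross-validation on the fitted cross-spectrum.
    lambdas : array-like or None
        GCV candidate grid; default spans the spectrum of KK'.
    normalize_depth : bool
        Scale each voxel's gain columns to unit Frobenius norm before
        inversion (mitigates the superficial-source bias of minimum-norm
        solutions) and undo the scaling on the output moments.
    per_bin : bool
        Select lambda (and build an operator) per frequency bin instead
        of one global lambda over all bins.

    Attributes (after ``fit``)
    --------------------------
    t_ : ndarray ((voxels*components), channels) — global operator
         (``per_bin=True`` stores ``t_per_bin_`` instead).
    lambda_ : float or ndarray — selected penalty.
    """

    def __init__(self, lam="gcv", lambdas=None, normalize_depth: bool = True,
                 per_bin: bool = False):
        self.lam = lam
        self.lambdas = lambdas
        self.normalize_depth = normalize_depth
        self.per_bin = per_bin

    def _scaled_gain(self, lf: LeadField) -> tuple[np.ndarray, np.ndarray]:
        k = lf.k
        ncomp = lf.n_components
        if not self.normalize_depth:
            return k, np.ones(k.shape[1])
        blocks = k.reshape(k.shape[0], lf.n_voxels, ncomp)
        norms = np.linalg.norm(blocks, axis=(0, 2))  # Frobenius per voxel
        if np.any(norms == 0):
            raise ValueError("zero gain block; voxel outside sensitivity")
        scale = np.repeat(norms, ncomp)
        return k / scale[None, :], scale

    def fit(self, lf: LeadField, cs: CrossSpectrum | None = None) -> "RidgeInverse":
        k, scale = self._scaled_gain(lf)
        self.voxel_xyz_ = lf.voxel_xyz
        self.n_components_ = lf.n_components
        if self.per_bin:
            if cs is None:
                raise ValueError("per-bin lambda selection needs a cross-spectrum")
            lams, ops = [], []
            cand = (np.asarray(self.lambdas, dtype=float)
                    if self.lambdas is not None else default_lambda_grid(k))
            for b in range(cs.grid.n_bins):
                if self.lam == "gcv":
                    curve = _gcv_curve(k, cs.s[b].real, np.sort(cand))
                    lam = float(np.sort(cand)[int(np.argmin(curve))])
                else:
                    lam = float(self.lam)
                lams.append(lam)
                ops.append(_ridge_solve(k, lam) / scale[:, None])
            self.lambda_ = np.asarray(lams)
            self.t_per_bin_ = np.asarray(ops)
            return self
        if self.lam == "gcv":
            if cs is None:
                raise ValueError("lam='gcv' needs a cross-spectrum at fit time")
            cand = (np.asarray(self.lambdas, dtype=float)
                    if self.lambdas is not None else default_lambda_grid(k))
            m = np.sum(cs.s.real, axis=0)
            if not np.any(m):
                raise ValueError("zero cross-spectrum: GCV is undefined")
            cand = np.sort(cand)
            curve = _gcv_curve(k, m, cand)
            self.lambda_ = float(cand[int(np.argmin(curve))])
        else:
            self.lambda_ = float(self.lam)
        self.t_ = _ridge_solve(k, self.lambda_) / scale[:, None]
        return self

    def transform(self, cs: CrossSpectrum) -> SourceSpectra:
        """Source power spectra for a fitted operator."""
        if self.per_bin:
            if not hasattr(self, "t_per_bin_"):
                raise ValueError("not fitted")
            powers = []
            for b in range(cs.grid.n_bins):
                op = InverseOperator(t=self.t_per_bin_[b], lam=self.lambda_[b])
                sub = CrossSpectrum(s=cs.s[b:b + 1],
                                    grid=FrequencyGrid(cs.grid.resolution_hz,
                                                       cs.grid.k[b:b + 1],
                                                       cs.grid.n_fft),
                                    n_epochs=cs.n_epochs, taper=cs.taper,
                                    channel_labels=cs.channel_labels)
                powers.append(source_spectra(op, sub, self.voxel_xyz_,
                                             self.n_components_).power[:, 0])
            return SourceSpectra(power=np.column_stack(powers), grid=cs.grid,
                                 voxel_xyz=self.voxel_xyz_)
        if not hasattr(self, "t_"):
            raise ValueError("not fitted")
        return source_spectra(self, cs, self.voxel_xyz_, self.n_components_)
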