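"""Age-regression normative models and z-spectra.

For every location (scalp channel or source voxel) and frequency bin, the
cohort's log10 spectral power is regressed on polynomials of
``u = log10(age)``; a second regression of log-absolute residuals on the
same basis gives a smooth, strictly positive age-dependent standard
deviation.  A subject's z-spectrum is then
``z = (y - mu(age)) / sigma(age)`` elementwise — the univariate normative
Statistical Parametric Map the clinician reads.

The SD regression works on absolute residuals with the half-normal
correction: for r ~ N(0, sigma), E[|r|] = sigma * sqrt(2/pi), so the
least-squares fit of ``|r| * sqrt(pi/2)`` on the age basis is consistent
for sigma(age); a floor keeps sigma strictly positive everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

#: sqrt(pi/2): E[|r|] of a centered Gaussian is sigma * sqrt(2/pi)
HALF_NORMAL_CORRECTION = float(np.sqrt(np.pi / 2.0))

LOG_EPS = 1e-12


def transform_spectra(power: np.ndarray) -> np.ndarray:
    """log10 transform of raw spectral power (with a 1e-12 floor)."""
    power = np.asarray(power, dtype=float)
    if np.any(power < 0):
        raise ValueError("raw power must be non-negative")
    return np.log10(power + LOG_EPS)


def logit_transform(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Logit for bounded-support measures (relative power)."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1 - eps)
    return np.log(p / (1 - p))


@dataclass
class ZMaps:
    """z values per location x frequency, with optional corrected cutoff."""

    z: np.ndarray                 # (location, bin)
    level: str                    # scalp | source
    age_used: float
    locations: Sequence[str]
    bin_hz: np.ndarray
    threshold: float | None = None
    alpha: float | None = None
    mask: np.ndarray | None = None  # |z| >= threshold

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z maps must be finite")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be positive")


class NormativeModel(BaseEstimator):
    """Polynomial-in-log-age normative mean and SD per location x bin.

    Parameters
    ----------
    degree : int
        Polynomial degree P in u = log10(age); default 3.
    state : str
        Recording state the norms describe (EC, EO or HV).
    level : str
        ``"scalp"`` or ``"source"``.
    sigma_floor : float
        Lower bound on sigma(age), log10-power units.
    gsf : str
        ``"two-pass"`` (default): fit preliminary norms, estimate each
        subject's Global Scale Factor against them, remove it, refit once.
        ``"off"`` skips the correction.
    store_residuals : bool
        Keep the cohort's residual z-fields (used by the empirical
        maximum-statistic threshold).

    Attributes (after ``fit``)
    --------------------------
    beta_mu_, beta_sigma_ : ndarray (location, bin, degree+1)
    locations_ : list of str
    grid_bin_hz_ : ndarray (bin,)
    age_range_ : (min, max) years seen in the cohort
    residual_z_ : ndarray (subject, location, bin) or None
    """

    def __init__(self, degree: int = 3, state: str = "EC", level: str = "scalp",
                 sigma_floor: float = 0.01, gsf: str = "two-pass",
                 store_residuals: bool = False):
        self.degree = degree
        self.state = state
        self.level = level
        self.sigma_floor = sigma_floor
        self.gsf = gsf
        self.store_residuals = store_residuals

    # -- fitting ----------------------------------------------------------

    def _design(self, ages: np.ndarray) -> np.ndarray:
        u = np.log10(ages)
        return np.vander(u, self.degree + 1, increasing=True)

    def fit(self, y: np.ndarray, ages: Sequence[float],
            locations: Sequence[str] | None = None,
            grid_bin_hz: np.ndarray | None = None) -> "NormativeModel":
        """Fit mean and SD age regressions on a cohort.

        Parameters
        ----------
        y : ndarray (subject, location, bin)
            Transformed (log10) spectra.
        ages : array of years, one per subject.
        """
        y = np.asarray(y, dtype=float)
        ages = np.asarray(ages, dtype=float)
        if y.ndim != 3:
            raise ValueError("y must be (subject, location, bin)")
        n, n_loc, n_bin = y.shape
        if ages.shape != (n,):
            raise ValueError("one age per subject required")
        if np.any(ages <= 0) or np.any(ages > 120):
            raise ValueError("ages must lie in (0, 120] years")
        if n < self.degree + 2:
            raise ValueError(
                f"need at least degree+2 = {self.degree + 2} subjects, got {n}")
        x = self._design(ages)
        if np.linalg.matrix_rank(x) < self.degree + 1:
            raise ValueError(
                "rank-deficient age design (too few distinct ages for "
                f"degree {self.degree})")

        flat = y.reshape(n, n_loc * n_bin)
        beta, *_ = np.linalg.lstsq(x, flat, rcond=None)
        if self.gsf == "two-pass":
            fitted = x @ beta
            gsf_per_subject = (flat - fitted).mean(axis=1)  # (n,)
            flat = flat - gsf_per_subject[:, None]
            beta, *_ = np.linalg.lstsq(x, flat, rcond=None)
            self.gsf_two_pass_ = True
        elif self.gsf == "off":
            self.gsf_two_pass_ = False
        else:
            raise ValueError("gsf must be 'two-pass' or 'off'")

        resid = flat - x @ beta
        # studentize: fitted residuals shrink by sqrt(1 - h_ii), most at
        # high-leverage (sparsely sampled) ages
        hat = np.einsum("ij,jk,ik->i", x, np.linalg.pinv(x.T @ x), x)
        student = 1.0 / np.sqrt(np.clip(1.0 - hat, 1e-3, None))
        target = np.abs(resid) * student[:, None] * HALF_NORMAL_CORRECTION
        beta_sigma, *_ = np.linalg.lstsq(x, target, rcond=None)

        self.beta_mu_ = beta.T.reshape(n_loc, n_bin, self.degree + 1)
        self.beta_sigma_ = beta_sigma.T.reshape(n_loc, n_bin, self.degree + 1)
        self.locations_ = (list(locations) if locations is not None
                           else [f"loc{i}" for i in range(n_loc)])
        self.grid_bin_hz_ = (np.asarray(grid_bin_hz, dtype=float)
                             if grid_bin_hz is not None
                             else np.arange(1, n_bin + 1, dtype=float))
        if self.grid_bin_hz_.shape[0] != n_bin:
            raise ValueError("grid_bin_hz length inconsistent with y")
        self.n_subjects_ = n
        self.age_range_ = (float(ages.min()), float(ages.max()))
        if self.store_residuals:
            sig = np.empty_like(resid)
            for i, age in enumerate(ages):
                _, s = self.predict(age, _warn=False)
                sig[i] = s.reshape(-1)
            self.residual_z_ = (resid / sig).reshape(n, n_loc, n_bin)
        else:
            self.residual_z_ = None
        return self

    # -- evaluation -------------------------------------------------------

    def predict(self, age: float, _warn: bool = True
                ) -> tuple[np.ndarray, np.ndarray]:
        """Normative (mu, sigma) arrays of shape (location, bin) at ``age``."""
        if not hasattr(self, "beta_mu_"):
            raise ValueError("model is not fitted")
        if age <= 0:
            raise ValueError("age must be positive")
        if _warn and not (self.age_range_[0] <= age <= self.age_range_[1]):
            warnings.warn(
                f"age {age} outside normative range {self.age_range_}; "
                "extrapolating", stacklevel=2)
        powers = np.power(np.log10(age), np.arange(self.degree + 1))
        mu = self.beta_mu_ @ powers
        sigma = np.maximum(self.beta_sigma_ @ powers, self.sigma_floor)
        return mu, sigma

    def transform(self, y: np.ndarray, age: float) -> np.ndarray:
        """z = (y - mu(age)) / sigma(age), elementwise."""
        y = np.asarray(y, dtype=float)
        mu, sigma = self.predict(age)
        if y.shape != mu.shape:
            raise ValueError(f"spectra shape {y.shape} != norms {mu.shape}")
        return (y - mu) / sigma

    def match_locations(self, labels: Sequence[str]) -> np.ndarray:
        """Indices into ``labels`` matching the model's locations.

        Case-insensitive and order-free; missing locations are an error,
        extra ones are dropped with a warning.
        """
        lower = {c.lower(): i for i, c in enumerate(labels)}
        missing = [c for c in self.locations_ if c.lower() not in lower]
        if missing:
            raise ValueError(f"channels required by norms are missing: {missing}")
        if len(labels) > len(self.locations_):
            extra = [c for c in labels
                     if c.lower() not in {x.lower() for x in self.locations_}]
            warnings.warn(f"extra channels dropped: {extra}", stacklevel=2)
        return np.array([lower[c.lower()] for c in self.locations_])


# -- module-level convenience wrappers --------------------------------------

def fit_norm_model(cohort, degree: int = 3, state: str = "EC",
                   level: str = "scalp", locations=None, grid_bin_hz=None,
                   **kwargs) -> NormativeModel:
    """Fit a :class:`NormativeModel` from ``[(transformed_spectra, age), ...]``."""
    y = np.stack([s for s, _ in cohort])
    ages = np.array([a for _, a in cohort], dtype=float)
    model = NormativeModel(degree=degree, state=state, level=level, **kwargs)
    return model.fit(y, ages, locations=locations, grid_bin_hz=grid_bin_hz)


def evaluate_norm(nm: NormativeModel, age: float):
    """(mu, sigma) at an age; warns when extrapolating outside the cohort."""
    return nm.predict(age)


def z_score(y: np.ndarray, nm: NormativeModel, age: float,
            state: str | None = None) -> ZMaps:
    """z-spectrum of transformed, GSF-corrected spectra against norms."""
    if state is not None and state != nm.state:
        warnings.warn(
            f"norms are for state {nm.state}, subject recorded in {state}",
            stacklevel=2)
    z = nm.transform(y, age)
    return ZMaps(z=z, level=nm.level, age_used=float(age),
                 locations=list(nm.locations_), bin_hz=nm.grid_bin_hz_)
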