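import numpy as np
import pytest

import qeegnorm as q


@pytest.fixture(scope="session")
def grid_200_512():
    """The canonical analysis grid: 2.56 s epochs at 200 Hz, 49 bins."""
    return q.build_frequency_grid(512, 200.0, 19.5)


@pytest.fixture(scope="session")
def montage19():
    return q.load_montage("10-20-19")


@pytest.fixture(scope="session")
def leadfield19(montage19):
    """Free-orientation spherical lead field on the coarse voxel grid."""
    return q.spherical_leadfield(montage19, grid_size=7)


@pytest.fixture(scope="session")
def fitted_norms(grid_200_512):
    """Norms fitted on the default synthetic cohort (n=211, ages 5-87)."""
    labels = [f"c{i}" for i in range(19)]
    spec = q.CohortSpec(seed=3)
    cohort = q.make_cohort(spec, grid_200_512, labels)
    y = np.stack([q.transform_spectra(p) for p, _ in cohort])
    ages = np.array([a for _, a in cohort])
    model = q.NormativeModel(degree=3, store_residuals=True)
    model.fit(y, ages, locations=labels, grid_bin_hz=grid_200_512.bin_hz)
    return spec, model


def random_epochs(seed, n_epochs=3, n_samples=64, n_channels=2, fs=64.0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_epochs, n_samples, n_channels))
    labels = [f"ch{i}" for i in range(n_channels)]
    return q.EpochSet(data=data, fs=fs, channel_labels=labels)
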