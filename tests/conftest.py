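import numpy as np
import pytest

from spectransfer.core import Dataset, SpectraSet
from spectransfer.synthetic_fixtures import FixtureConfig, generate_dataset_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spectra(rng) -> SpectraSet:
    wl = np.linspace(900.0, 1700.0, 12)
    X = 40.0 + 5.0 * rng.standard_normal((6, 12))
    return SpectraSet(X=X, wavelengths=wl, sample_ids=[f"s{i}" for i in range(6)])


@pytest.fixture(scope="session")
def fixture_pair_small():
    """Paired 100-sample, 60-band crushed/full datasets (session-cached)."""
    cs, fs, truth = generate_dataset_pair(FixtureConfig(seed=7, n_bands=60))
    return cs, fs, truth


def make_dataset(X, y, ids=None, form=None, wavelengths=None) -> Dataset:
    X = np.asarray(X, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(X.shape[1], dtype=float) + 1000.0
    if ids is None:
        ids = [f"s{i}" for i in range(X.shape[0])]
    return Dataset(SpectraSet(X, wavelengths, ids, form=form), np.asarray(y, dtype=float))
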