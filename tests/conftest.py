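import numpy as np
import pytest

from lwcspec.spectra import SpectraSet, TraitVector, trim_default_windows
from lwcspec.synth import SyntheticConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_set(rng):
    """10 random positive spectra on a small contiguous grid."""
    wl = np.arange(700, 720)
    vals = 0.2 + 0.6 * rng.random((10, wl.size))
    return SpectraSet(wl, vals, tuple(f"s{i}" for i in range(10)))


@pytest.fixture
def flat_set():
    """Three constant spectra at 0.5 covering every moisture-index band."""
    wl = np.arange(400, 2401)
    vals = np.full((3, wl.size), 0.5)
    return SpectraSet(wl, vals, ("a", "b", "c"))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic dataset (n=60) for mid-weight integration tests."""
    return make_dataset(SyntheticConfig(n=60, seed=7))


@pytest.fixture(scope="session")
def small_trimmed(small_dataset):
    return trim_default_windows(small_dataset.spectra), small_dataset.trait
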