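import numpy as np
import pytest

import specdemux as sd


@pytest.fixture(scope="session")
def grid61():
    """The default 61-point 410-710 nm grid."""
    return sd.make_wavelength_grid()


@pytest.fixture(scope="session")
def sens(grid61):
    """Default synthetic 3x61 Gaussian filter-bank sensitivity."""
    return sd.synth_sensitivity(grid61)


@pytest.fixture(scope="session")
def small_pairs(sens, grid61):
    """A small training set for quick forest fits."""
    cfg = sd.SpectraGenConfig(n_spectra=200, seed=5, grid=grid61)
    return sd.generate_training_pairs(sens, cfg)


@pytest.fixture(scope="session")
def small_forest(small_pairs):
    return sd.train_forest(small_pairs, n_trees=30, seed=3)


@pytest.fixture(scope="session")
def small_wiener(sens, grid61):
    cfg = sd.SpectraGenConfig(n_spectra=200, seed=5, grid=grid61)
    return sd.train_wiener(sd.generate_random_spectra(cfg), sens)


@pytest.fixture(scope="session")
def reduced_pairs(sens, grid61):
    """Reduced-scale training set: 2,000 spectra, seed 42."""
    cfg = sd.SpectraGenConfig(n_spectra=2000, seed=42, grid=grid61)
    return sd.generate_training_pairs(sens, cfg)


@pytest.fixture(scope="session")
def reduced_forest(reduced_pairs):
    """DEMUX-RFM at the reduced scale: 300 trees, seed 7."""
    return sd.train_forest(reduced_pairs, n_trees=300, seed=7)


@pytest.fixture(scope="session")
def reduced_wiener(reduced_pairs, sens):
    """DEMUX-WEM trained on the same reduced-scale spectra."""
    return sd.train_wiener([s for _, s in reduced_pairs], sens)


def random_reflectance(grid, rng):
    return sd.ReflectanceSpectrum(grid, rng.uniform(0.0, 1.0, len(grid)))
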