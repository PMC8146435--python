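import numpy as np
import pytest

from nitrospec import GeneratorConfig, generate_dataset, preprocess
from nitrospec.dataset import SpectralDataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic dataset (400 samples, seed 7)."""
    return generate_dataset(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def preprocessed_dataset(default_dataset):
    prepared, _ = preprocess(default_dataset)
    return prepared


@pytest.fixture(scope="session")
def planted_band_indices(preprocessed_dataset):
    wl = preprocessed_dataset.wavelengths
    return [int(np.argmin(np.abs(wl - c))) for c in (723.0, 781.0, 901.0)]


@pytest.fixture
def tiny_dataset():
    """Hand-sized reflectance dataset: 3 samples, 4 wavelengths."""
    return SpectralDataset(
        wavelengths=[500.0, 600.0, 700.0, 800.0],
        values=[[0.2, 0.3, 0.5, 0.8],
                [0.25, 0.35, 0.55, 0.85],
                [0.1, 0.2, 0.4, 0.7]],
        labels=["D0", "D1", "D0"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
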