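import numpy as np
import pytest

from wheatn.spectra import ReflectanceSpectrum
from wheatn.synthetic import ExperimentConfig, generate_experiment


@pytest.fixture(scope="session")
def small_dataset():
    """12-plot two-stage dataset shared across read-only tests."""
    return generate_experiment(ExperimentConfig(n_plots=12, seed=7))


@pytest.fixture
def flat_spectrum():
    wl = np.arange(350, 2501)
    return ReflectanceSpectrum(wavelengths=wl, values=np.full(wl.size, 0.3))


def make_spectrum(bands: dict, default: float = 0.2) -> ReflectanceSpectrum:
    """Full-range spectrum with specified reflectance at given integer bands."""
    wl = np.arange(350, 2501)
    vals = np.full(wl.size, default)
    for b, v in bands.items():
        vals[b - 350] = v
    return ReflectanceSpectrum(wavelengths=wl, values=vals)
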