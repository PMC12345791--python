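import numpy as np
import pytest

from qusr.rf_synth import PulseModel, simulate_reference_phantom
from qusr.spectra import SpectralConfig


@pytest.fixture(scope="session")
def pulse():
    return PulseModel()


@pytest.fixture(scope="session")
def spectral_config():
    return SpectralConfig()


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced frame geometry for fast tests."""
    return dict(depth_mm=20.0, n_lines=64, line_pitch_mm=0.23)


@pytest.fixture(scope="session")
def reference(pulse):
    return simulate_reference_phantom(pulse, known_attenuation=0.3, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
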