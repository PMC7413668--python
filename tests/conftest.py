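import numpy as np
import pytest

from thetasync import synth
from thetasync.decompose import fit_decomposition
from thetasync.pipeline import default_laminar_specs

FS = 625.0


@pytest.fixture(scope="session")
def laminar():
    """Three-generator laminar fixture with ground truth (60 s, low noise)."""
    specs = default_laminar_specs()
    rec, truth = synth.simulate_laminar_lfp(
        specs, duration=60.0, noise_level=0.05, fs=FS, seed=3
    )
    return specs, rec, truth


@pytest.fixture(scope="session")
def laminar_dec(laminar):
    _, rec, _ = laminar
    return fit_decomposition(rec, seed=0)


@pytest.fixture(scope="session")
def theta_fixture():
    """Clean-ish calibration signal (high theta amplitude)."""
    model = synth.ThetaNoiseModel(amplitude=4.0, duration=60.0, fs=FS, seed=7)
    x, troughs, phase = synth.simulate_theta_noise(model)
    return model, x, troughs, phase


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
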