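import numpy as np
import pytest

import perisinus as ps


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic noiseless phantom shared across tests."""
    spec = ps.PhantomSpec(noise_sd=0.0, bias_amplitude=0.0, seed=7)
    vol, lab, truth = ps.generate_phantom(spec)
    return spec, vol, lab, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = ps.PhantomSpec(seed=11)
    vol, lab, truth = ps.generate_phantom(spec)
    return spec, vol, lab, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def identity_volume(shape=(16, 16, 16), seed=0, space="native"):
    rng = np.random.default_rng(seed)
    data = rng.normal(50, 10, shape).astype(np.float32)
    return ps.Volume3D(data, (1.0, 1.0, 1.0), np.eye(4), space)
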