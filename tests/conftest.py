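import numpy as np
import pytest

from adscfgwo.phantoms import PhantomConfig, generate_phantom_dataset


class QueuedRNG:
    """Stub random source that replays queued draws, for forcing coefficients."""

    def __init__(self, draws):
        self._draws = list(draws)

    def random(self, size=None):
        value = self._draws.pop(0)
        if size is None:
            return float(np.asarray(value).ravel()[0])
        return np.broadcast_to(np.asarray(value, dtype=float), (size,)).copy()


@pytest.fixture
def queued_rng():
    return QueuedRNG


@pytest.fixture(scope="session")
def small_phantoms():
    """60 noiseless 64x64 phantoms, half tumor."""
    return generate_phantom_dataset(PhantomConfig(n_images=60, seed=7))


@pytest.fixture(scope="session")
def tuning_phantoms():
    """200 noiseless separable 64x64 phantoms, the standard tuning testbed."""
    return generate_phantom_dataset(PhantomConfig(n_images=200, seed=3, noise_sd=0.0))
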