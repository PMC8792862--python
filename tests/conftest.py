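import numpy as np
import pytest

from ushapegan import PhantomConfig, generate_phantoms


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """16 noisy phantoms at the minimum resolution, with exact masks."""
    return generate_phantoms(PhantomConfig(resolution=32, n_images=16, seed=7))


@pytest.fixture(scope="session")
def tiny_arrays(tiny_phantoms):
    X = np.stack([p.pixels for p in tiny_phantoms])
    Y = np.stack([p.mask for p in tiny_phantoms]).astype(np.int64)
    return X, Y


def random_prob_maps(rng, n=3, h=8, w=8, channels=3):
    """Valid random probability maps: Dirichlet-like via normalized uniforms."""
    raw = rng.uniform(0.01, 1.0, size=(n, channels, h, w))
    return raw / raw.sum(axis=1, keepdims=True)
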