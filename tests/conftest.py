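import numpy as np
import pytest

from nlscfcm import make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_model_instance(seed, shape=(6, 6), c=2):
    """A random small instance of every quantity the model objective
    takes: image x, nonlocal map y, memberships u, centers v, bias b,
    weight factor S, trade-off alpha."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.1, 1.0, size=shape)
    y = x + rng.normal(0, 0.05, size=shape)
    u = rng.uniform(0.05, 1.0, size=(c,) + shape)
    u /= u.sum(axis=0)
    v = np.sort(rng.uniform(0.1, 1.0, size=c))
    while c > 1 and np.min(np.diff(v)) < 0.05:
        v = np.sort(rng.uniform(0.1, 1.0, size=c))
    b = rng.uniform(0.7, 1.3, size=shape)
    s_map = rng.uniform(0.0, 0.95, size=(c,) + shape)
    alpha = rng.uniform(0.2, 1.0, size=shape)
    return x, y, u, v, b, s_map, alpha


@pytest.fixture
def clean_phantom():
    """Noiseless, bias-free 3-class phantom with ground truth."""
    return make_dataset(shape=(64, 64), class_intensities=(0, 100, 200),
                        bias_amplitude=0.0, noise_percent=0.0, seed=0)


@pytest.fixture
def noisy_phantom():
    """Standard noisy biased phantom (3% noise, 20% inhomogeneity)."""
    return make_dataset(shape=(64, 64), bias_amplitude=0.2,
                        noise_percent=0.03, seed=1)
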