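import numpy as np
import pytest

from rfeunet import PhantomSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small canvas phantom family used across pipeline tests."""
    return PhantomSpec(image_size=64)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec, n=8, seed=42, split=0.5)


def numerical_grad(fn, arrays, eps=1e-5):
    """Central-difference gradients of scalar fn w.r.t. a list of float64 arrays."""
    grads = []
    for a in arrays:
        g = np.zeros_like(a)
        flat = a.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            up = fn()
            flat[i] = orig - eps
            down = fn()
            flat[i] = orig
            gflat[i] = (up - down) / (2 * eps)
        grads.append(g)
    return grads
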