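import numpy as np
import pytest

from lkdanet import default_config
from lkdanet.synthetic_data import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """A narrow architecture that keeps CPU tests fast."""
    return default_config(2, stage_channels=(4, 8, 16, 32, 64),
                          stage_depths=(1, 1, 1, 1), se_reduction=2)


@pytest.fixture(scope="session")
def small_phantom():
    """24³ two-class phantom (background + one organ), fixed seed."""
    return generate_phantom(PhantomSpec(size=(24, 24, 24), n_classes=1,
                                        noise_sd=0.1, seed=1,
                                        min_organ_radius=4,
                                        max_organ_radius=8))


def numerical_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an ndarray."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = f(x)
        x[idx] = orig - eps
        lo = f(x)
        x[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
    return g
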