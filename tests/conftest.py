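import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_model_cfg():
    """Width-halved model on a small grid: cheap enough for unit tests."""
    from lmunet.network import ModelConfig

    return ModelConfig(stage_channels=(4, 8, 12, 16, 24, 32), image_size=64,
                       ema_groups=4, seed=7)


def finite_difference(f, x, idx, eps=1e-6):
    """Central difference of scalar-valued f at one coordinate of x."""
    xp = x.copy()
    xp[idx] += eps
    xm = x.copy()
    xm[idx] -= eps
    return (f(xp) - f(xm)) / (2 * eps)
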