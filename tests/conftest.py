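import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    from rewardlight.volumes import VoxelGrid

    return VoxelGrid((12, 12, 8))


@pytest.fixture
def full_mask(small_grid):
    from rewardlight.volumes import MaskVolume

    return MaskVolume(small_grid, np.ones(small_grid.dims, dtype=bool), "full")


@pytest.fixture
def separable_features(rng):
    """1-D features with patients far above controls, labels attached."""
    n = 10
    labels = np.concatenate([np.ones(n, dtype=int), -np.ones(n, dtype=int)])
    x = np.concatenate([5.0 + rng.standard_normal(n), -5.0 + rng.standard_normal(n)])
    return x[:, None], labels
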