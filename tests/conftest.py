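import numpy as np
import pytest

from grapeboost.boost import GrapeBoost
from grapeboost.synth import SceneSpec, generate_samples, generate_scene


@pytest.fixture(scope="session")
def train_samples():
    """Default synthetic training set: 400 grape / 800 background windows."""
    return generate_samples(seed=0)


@pytest.fixture(scope="session")
def fitted(train_samples):
    """Boosted classifier trained on the default fixture."""
    return GrapeBoost(train_samples).fit()


@pytest.fixture(scope="session")
def scene0():
    """Deterministic two-cluster scene with ground truth."""
    spec = SceneSpec(seed=0)
    image, mask, boxes = generate_scene(spec)
    return spec, image, mask, boxes


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
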