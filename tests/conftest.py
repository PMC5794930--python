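import numpy as np
import pytest

from pixelspec import SceneConfig, make_study


@pytest.fixture(scope="session")
def small_cfg() -> SceneConfig:
    """Scaled-down study: 4 classes x 3 scenes x 8 beans on 96x120 frames."""
    return SceneConfig(rows=96, cols=120, beans_per_scene=8, scenes_per_class=3,
                       seed=11)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return make_study(small_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
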