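import numpy as np
import pytest

from rowturn.config import PipelineConfig
from rowturn.synthetic_scenes import SceneConfig, render_scene


@pytest.fixture(scope="session")
def clean_scene():
    """Clutter-free forward-looking scene: 3 straight rows, exact depth."""
    cfg = SceneConfig(seed=3, straw_streaks=0, shadow_strength=0.0,
                      missing_plant_prob=0.0)
    return render_scene(cfg)


@pytest.fixture(scope="session")
def tilted_scene():
    """Low-clutter scene with rows angled 70 deg to the lateral axis."""
    cfg = SceneConfig(seed=11, row_azimuth_deg=70.0, straw_streaks=6,
                      shadow_strength=0.10, missing_plant_prob=0.02)
    return render_scene(cfg)


@pytest.fixture()
def default_config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
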