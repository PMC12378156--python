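import numpy as np
import pytest

from canopyscale.scene import (
    SceneConfig,
    generate_scene,
    make_footprint_features,
    sample_plots,
)


@pytest.fixture(scope="session")
def default_config():
    return SceneConfig()


@pytest.fixture(scope="session")
def default_scene(default_config):
    return generate_scene(default_config)


@pytest.fixture(scope="session")
def default_footprints(default_scene):
    return make_footprint_features(default_scene)


@pytest.fixture(scope="session")
def default_plots(default_scene, default_footprints):
    return sample_plots(default_scene, footprints=default_footprints)


@pytest.fixture(scope="session")
def large_footprints():
    """A >= 5000-footprint table for sampling-error-sensitive checks."""
    cfg = SceneConfig(grid_rows=256, grid_cols=256, n_footprint_tracks=66)
    scene = generate_scene(cfg)
    return make_footprint_features(scene), scene


@pytest.fixture(scope="session")
def recovery_scene():
    """The ~1000-footprint spatially-varying-coefficient recovery scene."""
    cfg = SceneConfig(grid_rows=192, grid_cols=192, n_footprint_tracks=18, seed=42)
    scene = generate_scene(cfg)
    return scene, make_footprint_features(scene)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
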