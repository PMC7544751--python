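import numpy as np
import pytest

from handdose.scene import SceneConfig, build_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_scene():
    return build_scene(SceneConfig())


@pytest.fixture(scope="session")
def full_fill_scene():
    """Scene with the liquid column filling the whole barrel (centred)."""
    return build_scene(SceneConfig(fill_length=10.0))
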