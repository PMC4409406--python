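import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20_150_317)


@pytest.fixture
def small_arena():
    from aquatrack.trajectory import ArenaConfig

    return ArenaConfig(width_cm=40.0, height_cm=40.0, margin_cm=4.0)


@pytest.fixture
def small_scene(small_arena):
    from aquatrack.synthetic import SceneConfig

    return SceneConfig(arena=small_arena, px_per_cm=5.0)
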