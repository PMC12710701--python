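import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def primitive():
    from eyevo.genome import primitive_genotype

    return primitive_genotype()


@pytest.fixture
def detection_spec():
    from eyevo.world import TaskSpec

    return TaskSpec.detection(episode_steps=100)


@pytest.fixture
def dead_ahead_spec():
    from eyevo.world import TaskSpec

    return TaskSpec.detection(spawn_mode="dead_ahead", episode_steps=100)
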