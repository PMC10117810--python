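import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from filamentry import PreprocessConfig, SyntheticColonySpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_config() -> PreprocessConfig:
    """Preprocessing config matched to the default synthetic frame."""
    return PreprocessConfig(target_resolution=(640, 480), opening_radius_px=12)


@pytest.fixture
def colony_spec() -> SyntheticColonySpec:
    return SyntheticColonySpec(rng_seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
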