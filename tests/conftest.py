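import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from enose.synth import GeneratorConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A fast campaign: 6 apples per class, full 350 s grid."""
    return GeneratorConfig(n_per_class=6, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The study-sized campaign: 4 classes x 40 samples."""
    return generate_dataset(GeneratorConfig(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
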