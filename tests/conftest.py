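import numpy as np
import pytest

from denomcast.simulate import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down synthetic study: fast, but exercises every stage."""
    return GeneratorConfig(n_centres=8, months_range=(2, 18), seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic scenario (study conditions at full size)."""
    return generate_study(GeneratorConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
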