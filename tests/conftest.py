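import numpy as np
import pytest

from depthtone import (AudioConfig, GridConfig, TransformSpec,
                       build_lookup_table, build_schedule, default_tone_bank)


@pytest.fixture(scope="session")
def linear_lut():
    return build_lookup_table(TransformSpec("linear"))


@pytest.fixture(scope="session")
def bank():
    return default_tone_bank()


@pytest.fixture(scope="session")
def schedule():
    return build_schedule()


@pytest.fixture(scope="session")
def grid_config():
    return GridConfig()


@pytest.fixture(scope="session")
def audio22():
    """22050 Hz output config (the device's target rate) to keep synthesis cheap."""
    return AudioConfig(sample_rate=22050)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
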