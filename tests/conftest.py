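import numpy as np
import pytest

from cestkit import (
    PhantomConfig,
    SuperLorentzianTable,
    build_protocol_offset_schedule,
    make_phantom,
)
from cestkit.phantom import default_region_params


@pytest.fixture(scope="session")
def schedule():
    return build_protocol_offset_schedule()


@pytest.fixture(scope="session")
def sl_table():
    return SuperLorentzianTable()


@pytest.fixture(scope="session")
def tz_params():
    return default_region_params()["tz"]


@pytest.fixture(scope="session")
def small_truth():
    """Small noiseless phantom with a flat B0 field (fast fixture)."""
    return make_phantom(
        PhantomConfig(shape=(24, 24), noise_sigma=0.0, b0_amplitude_ppm=0.0), seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
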