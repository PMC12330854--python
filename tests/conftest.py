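import numpy as np
import pytest

from urgepfm import hemo, synthgen


@pytest.fixture(scope="session")
def schedule():
    return synthgen.make_block_schedule()


@pytest.fixture(scope="session")
def hrf():
    return hemo.canonical_hrf(1800.0)


@pytest.fixture(scope="session")
def urge_blinks(schedule):
    return synthgen.simulate_urge_and_blinks(schedule, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
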