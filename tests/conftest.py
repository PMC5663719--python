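import numpy as np
import pytest

from songchairs.song_tasks import task_library
from songchairs.synthetic_data import SynthConfig


@pytest.fixture(scope="session")
def tasks():
    return task_library()


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
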