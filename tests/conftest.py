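import numpy as np
import pytest

from petkin import synthetic as syn
from petkin.synthetic import default_frame_schedule, default_aif, default_ground_truth


@pytest.fixture(scope="session")
def truths():
    return default_ground_truth()


@pytest.fixture(scope="session")
def frames():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def aif(frames):
    return default_aif(float(frames[1][-1]) + 1.0)


@pytest.fixture(scope="session")
def putamen_tac(truths, aif, frames):
    return syn.simulate_tac(truths["putamen"], aif, frames)


@pytest.fixture(scope="session")
def cerebellum_tac(truths, aif, frames):
    return syn.simulate_tac(truths["cerebellum"], aif, frames)
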