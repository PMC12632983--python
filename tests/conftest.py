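import numpy as np
import pytest

from wmref.kinetics import FrameSchedule, OneTCMContext
from wmref.phantom import (
    KineticTruth,
    PhantomSpec,
    build_phantom,
    simulate_input_function,
)
from wmref.roi import cs_analogue_mask, make_fbwm_series, make_wm_map


@pytest.fixture(scope="session")
def labels():
    """Default 90^3 phantom label volume (built once per session)."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def truth():
    return KineticTruth.default()


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def cp(schedule):
    return simulate_input_function(schedule=schedule)


@pytest.fixture(scope="session")
def ctx(cp, schedule):
    return OneTCMContext(cp, schedule)


@pytest.fixture(scope="session")
def wm_map(labels):
    return make_wm_map(labels, "cerebral_wm")


@pytest.fixture(scope="session")
def fbwm_series(labels):
    return make_fbwm_series(labels)


@pytest.fixture(scope="session")
def cs_mask(labels):
    return cs_analogue_mask(labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
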