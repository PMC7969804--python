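import numpy as np
import pytest

from oculoseason import SubjectParams
from oculoseason.stimulus import (
    make_antisaccade_schedule,
    make_pursuit_schedule,
    make_visually_guided_schedule,
)


@pytest.fixture(scope="session")
def noise_free_params() -> SubjectParams:
    return SubjectParams(gaze_noise_deg=0.0, landing_noise_deg=0.0,
                         premature_rate=0.0, latency_sd_ms=0.0)


@pytest.fixture(scope="session")
def vgs_schedule():
    return make_visually_guided_schedule(seed=1)


@pytest.fixture(scope="session")
def pursuit_schedule():
    return make_pursuit_schedule()


@pytest.fixture(scope="session")
def anti_schedule():
    return make_antisaccade_schedule(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
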