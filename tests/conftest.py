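import numpy as np
import pytest
from hypothesis import settings

from gcsim import ModelParams, RateParams, ScheduleParams

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20210331)


@pytest.fixture
def small_params():
    """A cheap configuration: short horizon, small carrying capacity."""
    return ModelParams(
        schedule=ScheduleParams(t_end=6.0, shm_start_day=4.0),
        rates=RateParams(capacity=500.0),
    )
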