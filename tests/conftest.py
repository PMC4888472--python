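import numpy as np
import pytest

from nsdlsm.simulate import SIM_EPOCH
from nsdlsm.trajectory import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20160901)


def daily_trajectory(xy: np.ndarray, animal_id: str = "a") -> Trajectory:
    n = xy.shape[0]
    times = (
        SIM_EPOCH + np.arange(n).astype("timedelta64[D]")
    ).astype("datetime64[ns]") + np.timedelta64(12, "h")
    return Trajectory(animal_id, times, xy[:, 0], xy[:, 1], daily=True)


@pytest.fixture
def make_daily_trajectory():
    return daily_trajectory
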