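import numpy as np
import pandas as pd
import pytest

from gaitmon.calibrate import train_synthetic_model
from gaitmon.gait import GaitWindow

T0 = pd.Timestamp("2018-03-01 09:00:00", tz="UTC")


@pytest.fixture(scope="session")
def speed_model():
    """A synthetic-calibrated speed model shared across tests."""
    return train_synthetic_model(seed=7, n_walks=40, walk_s=30.0)


def make_gait_window(
    start_s: float,
    fx: float = 2.0,
    steps: float | None = None,
    speed: float = 1.0,
    duration_s: float = 2.5,
) -> GaitWindow:
    """Bare walking window for bout/summary unit tests (no raw signal)."""
    gw = GaitWindow(
        window=None,
        start_time_s=start_s,
        duration_s=duration_s,
        F_hz=np.array([fx, fx / 2, fx / 2]),
        A_g=np.array([0.2, 0.1, 0.1]),
        speed_mps=speed,
    )
    gw.step_contribution = steps if steps is not None else fx * duration_s / 2
    return gw


@pytest.fixture
def mk_gw():
    return make_gait_window
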