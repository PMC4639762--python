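import numpy as np
import pytest

from multipet import protocol, tac
from multipet.cohort import cohort_feature_table, make_toy_atlas, simulate_cohort


@pytest.fixture(scope="session")
def grid():
    return tac.default_grid_min()


@pytest.fixture(scope="session")
def input_fn():
    return tac.InputFunction()


@pytest.fixture(scope="session")
def ded_schedule():
    return protocol.FRAME_SCHEDULES["DED"]


@pytest.fixture(scope="session")
def noise_free_pair(grid, input_fn, ded_schedule):
    """Noise-free target (2TCM, k3 = 0.05) and reference (weak trapping) TACs."""
    target = tac.sample_frames(
        grid, tac.tissue_tac(tac.KineticParams(0.3, 0.2, 0.05), input_fn, grid), ded_schedule
    )
    ref = tac.sample_frames(
        grid, tac.tissue_tac(tac.KineticParams(0.3, 0.2, 0.01), input_fn, grid), ded_schedule
    )
    return target, ref


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas((16, 16, 16))


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(master_seed=123)


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return cohort_feature_table(default_cohort)
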