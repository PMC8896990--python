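import numpy as np
import pytest

from connpattern.synthetic import SyntheticCohortConfig, generate_cohort

from _utils import white_noise_timeseries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_ts(rng):
    return white_noise_timeseries(rng)


@pytest.fixture(scope="session")
def small_cohort():
    config = SyntheticCohortConfig(
        n_patients=6,
        n_controls=4,
        sessions=("W1", "W4", "W12"),
        n_volumes=210,
        missing_rate=0.0,
        seed=7,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def voxel_cohort():
    config = SyntheticCohortConfig(
        n_patients=2,
        n_controls=2,
        sessions=("W1",),
        n_volumes=120,
        missing_rate=0.0,
        voxels_per_roi=6,
        seed=11,
    )
    return generate_cohort(config)
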