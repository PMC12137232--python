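import numpy as np
import pytest

from gsrpipe.parcellation import make_parcellation
from gsrpipe.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def scheme():
    return make_parcellation()


@pytest.fixture(scope="session")
def roi_cfg():
    """ROI-level (no voxel expansion) default-condition config."""
    return SimulationConfig(seed=42, n_voxels_per_roi=1)


@pytest.fixture(scope="session")
def roi_cohort(roi_cfg, scheme):
    return simulate_cohort(roi_cfg, scheme)


@pytest.fixture()
def small_rng():
    # function-scoped so every test sees the same stream regardless of
    # which other tests ran before it
    return np.random.default_rng(12345)
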