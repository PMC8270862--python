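import numpy as np
import pytest

from synodce.aif import AIFParameters, plasma_aif
from synodce.synthetic import (AcquisitionSpec, PhantomSpec, generate_phantom,
                               supersampled_time_grid)


@pytest.fixture(scope="session")
def acq_demo() -> AcquisitionSpec:
    """Demo-scale acquisition: 32x32x8 grid, default protocol."""
    return AcquisitionSpec(grid_shape=(32, 32, 8), voxel_size=(5.0, 5.0, 4.0))


@pytest.fixture(scope="session")
def time_and_cp(acq_demo):
    """Supersampled minute grid, frame indices, and plasma AIF at Hct 0.42."""
    t_fine, obs_idx = supersampled_time_grid(acq_demo)
    cp = plasma_aif(t_fine, 0.42,
                    AIFParameters(bolus_arrival_offset=acq_demo.bolus_arrival_min))
    return t_fine, obs_idx, cp


@pytest.fixture(scope="session")
def phantom_demo():
    return generate_phantom(
        PhantomSpec(grid_shape=(32, 32, 8), voxel_size=(5.0, 5.0, 4.0)), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
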