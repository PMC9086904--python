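import numpy as np
import pytest

from morphnet.kls_network import GridSpec
from morphnet.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(n_points=128)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small three-group cohort reused across read-only tests."""
    spec = CohortSpec(group_sizes={"SleET": 3, "NorET": 3, "HC": 3},
                      n_rois=12, voxels_per_roi=(40, 80), seed=11)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
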