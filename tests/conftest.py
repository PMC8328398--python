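import logging

import numpy as np
import pytest

import octradiomics as o

# the reduced volume shape used throughout the suite: big enough for a
# 5-slice central window and multi-hundred-voxel fluid pockets, small
# enough that full 962-descriptor extraction takes well under a second
TEST_SHAPE = (12, 48, 32)

logging.getLogger("octradiomics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def manifest():
    return o.default_manifest()


@pytest.fixture(scope="session")
def tiny_spec():
    return o.CohortSpec(
        n_rebounder=2, n_nonrebounder=2, volume_shape=TEST_SHAPE, seed=7
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return o.generate_cohort(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
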