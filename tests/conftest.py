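import numpy as np
import pytest

from lesionfactors import synth


@pytest.fixture(scope="session")
def template():
    """Small default-geometry template shared across tests."""
    return synth.make_template(grid_shape=(32, 36, 32), voxel_mm=(2.0, 2.0, 2.0), seed=0)


@pytest.fixture(scope="session")
def atlas(template):
    return synth.make_atlas(template, n_tracts=6, streamlines_per_tract=10, seed=1)


@pytest.fixture(scope="session")
def default_template():
    """Template at the full default grid (used for parcel-count checks)."""
    return synth.make_template(seed=0)
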