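import numpy as np
import pytest

from ieegloc.synthetic import make_head


@pytest.fixture(scope="session")
def head():
    """Default phantom: R_pial 60, R_white 50, 8 wedges, 1 mm voxels."""
    return make_head()


@pytest.fixture(scope="session")
def small_head():
    """Cheap phantom for IO/viz/CLI tests."""
    return make_head(
        R_pial=30.0,
        R_white=24.0,
        n_wedges=4,
        subcortical=(((-9.0, 0.0, 0.0), 5.0), ((9.0, 0.0, 0.0), 5.0)),
        voxel_mm=1.0,
        mesh_subdivisions=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
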