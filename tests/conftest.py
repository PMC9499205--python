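import numpy as np
import pytest

from ramusmorph.anatomy import build_planes, partition_ramus
from ramusmorph.synthetic import ShapeParams, generate_ramus


@pytest.fixture(scope="session")
def case_r():
    """A moderate-resolution right-side phantom without a volume (shared;
    treat as read-only)."""
    return generate_ramus(
        shape_params=ShapeParams(mesh_spacing_mm=0.55), side="R", seed=7, with_volume=False
    )


@pytest.fixture(scope="session")
def case_small():
    """A coarse phantom with a coarse volume, for volume-hungry tests."""
    return generate_ramus(
        shape_params=ShapeParams(mesh_spacing_mm=0.7),
        side="R",
        seed=11,
        voxel_spacing_mm=0.7,
    )


@pytest.fixture(scope="session")
def planes_r(case_r):
    return build_planes(case_r.landmarks, "R")


@pytest.fixture(scope="session")
def labeling_r(case_r, planes_r):
    return partition_ramus(case_r.preop_mesh, planes_r)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
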