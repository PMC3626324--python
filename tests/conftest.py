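import numpy as np
import pytest

from earlyfmt.mesh_model import (
    Mesh,
    PhantomSpec,
    PropertyField,
    build_cylindrical_phantom,
)

UNIT_TET = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)


@pytest.fixture
def unit_tet_mesh():
    return Mesh(UNIT_TET, np.array([[0, 1, 2, 3]]), np.array([0]))


@pytest.fixture
def two_tet_mesh():
    # two tets sharing face (0,1,2)
    coords = np.vstack([UNIT_TET, [[0.3, 0.3, -1.0]]])
    conn = np.array([[0, 1, 2, 3], [0, 1, 2, 4]])
    return Mesh(coords, conn, np.zeros(2, dtype=int))


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse homogeneous cylinder used by solver-level tests."""
    spec = PhantomSpec(organs=[], edge_length=0.45)
    return build_cylindrical_phantom(spec)


@pytest.fixture(scope="session")
def background_props():
    return PropertyField.from_tissue_table({0: "background"})
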