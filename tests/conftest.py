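import numpy as np
import pytest

import seegmorph as sm
from seegmorph import fixtures as fx


def brute_nearest(vertices, point):
    """Independent exhaustive nearest-vertex scan (pure python loop)."""
    best_i, best_d2 = 0, float("inf")
    for i, v in enumerate(vertices):
        d2 = float((v[0] - point[0]) ** 2 + (v[1] - point[1]) ** 2 + (v[2] - point[2]) ** 2)
        if d2 < best_d2:
            best_i, best_d2 = i, d2
    return best_i, best_d2 ** 0.5


@pytest.fixture(scope="session")
def sheet_spec():
    return fx.SheetSpec()


@pytest.fixture(scope="session")
def pair(sheet_spec):
    return fx.make_folded_pair(sheet_spec)


@pytest.fixture(scope="session")
def curv(sheet_spec):
    return fx.make_curvature(sheet_spec)


@pytest.fixture(scope="session")
def trajectory(sheet_spec):
    return fx.make_trajectory(fx.default_trajectory(sheet_spec))


@pytest.fixture(scope="session")
def mappings(pair, trajectory):
    return sm.map_contacts(pair, trajectory, 4.0)


@pytest.fixture
def tetrahedron():
    return sm.SurfaceMesh(
        np.array(
            [[0.0, 0.0, 0.0], [100.0, 0.0, 0.0], [0.0, 100.0, 0.0], [0.0, 0.0, 100.0]]
        ),
        np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]),
    )


def random_mesh(n_vertices, seed, scale=50.0):
    """A random point cloud wrapped as a mesh (one dummy face)."""
    rng = np.random.default_rng(seed)
    return sm.SurfaceMesh(
        rng.uniform(-scale, scale, (n_vertices, 3)), np.array([[0, 1, 2]])
    )
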