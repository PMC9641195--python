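import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ventrivol import TriangleMesh

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Unit cube [0,1]^3 with outward winding: 8 vertices, 12 faces.
CUBE_VERTICES = np.array(
    [
        (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
    ],
    dtype=float,
)
CUBE_FACES = np.array(
    [
        (0, 2, 1), (0, 3, 2),  # bottom, -z
        (4, 5, 6), (4, 6, 7),  # top, +z
        (0, 1, 5), (0, 5, 4),  # front, -y
        (2, 3, 7), (2, 7, 6),  # back, +y
        (0, 4, 7), (0, 7, 3),  # left, -x
        (1, 2, 6), (1, 6, 5),  # right, +x
    ],
    dtype=np.int64,
)


@pytest.fixture
def unit_cube():
    return TriangleMesh(CUBE_VERTICES.copy(), CUBE_FACES.copy(), name="cube")


@pytest.fixture
def cube_10mm():
    return TriangleMesh(CUBE_VERTICES * 10.0, CUBE_FACES.copy(), name="cube10")


def divergence_theorem_volume(mesh: TriangleMesh) -> float:
    """Independent volume oracle: surface integral sum A_f (c_f . n_f) / 3.

    Computed from face areas, centroids and unit normals — a different
    arithmetic route than the signed-tetrahedron summation it checks.
    """
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(cross, axis=1)
    keep = norms > 0
    areas = 0.5 * norms[keep]
    unit_n = cross[keep] / norms[keep, None]
    centroids = tri[keep].mean(axis=1)
    return float(np.sum(areas * np.einsum("ij,ij->i", centroids, unit_n)) / 3.0)


def random_closed_mesh(rng: np.random.Generator) -> TriangleMesh:
    """Random watertight, outward-oriented convex triangulation."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(rng.integers(12, 40), 3))
    pts = pts * rng.uniform(5.0, 40.0, size=3) + rng.uniform(-50.0, 50.0, size=3)
    hull = ConvexHull(pts)
    faces = hull.simplices.copy()
    interior = pts[hull.vertices].mean(axis=0)
    tri = pts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    inward = np.einsum("ij,ij->i", normals, tri.mean(axis=1) - interior) < 0
    faces[inward] = faces[inward][:, ::-1]
    return TriangleMesh(pts, faces, name="hull")
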