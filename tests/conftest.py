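"""Shared fixtures and geometry helpers for the test suite."""

import numpy as np
import pytest

from facedev.mesh_core import TriangleMesh
from facedev.synthetic_faces import (
    FaceParams,
    PerturbationSpec,
    derive_pair,
    generate_face,
)

# Reduced-resolution settings used throughout the suite for speed; the
# default resolution (128) is exercised once in test_synthetic.
TEST_RESOLUTION = 48
TEST_MIN_REGION_VERTICES = 3


def make_tetrahedron() -> TriangleMesh:
    """Unit tetrahedron, outward-facing winding."""
    v = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f)


def make_icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
    """Subdivided icosahedron: 20 * 4**s faces (1280 for s=3)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v / np.linalg.norm(v)) for v in verts]
    for _ in range(subdivisions):
        cache: dict = {}
        new_faces = []

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = np.asarray(verts[i]) + np.asarray(verts[j])
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return TriangleMesh(np.asarray(verts) * radius, np.asarray(faces))


def random_mesh(rng: np.random.Generator, n_faces_max: int = 500) -> TriangleMesh:
    """A random connected-ish triangle soup for oracle comparisons."""
    n_pts = rng.integers(6, 60)
    pts = rng.uniform(-10, 10, size=(int(n_pts), 3))
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    mesh = TriangleMesh(pts, hull.simplices)
    if mesh.n_faces > n_faces_max:
        mesh = TriangleMesh(pts, hull.simplices[:n_faces_max])
    return mesh


def brute_force_closest(query: np.ndarray, mesh: TriangleMesh) -> float:
    """Independent oracle: scalar per-triangle minimisation over all faces.

    Uses a formulation different from the package's (projection onto the
    triangle plane followed by explicit edge clamping).
    """
    best = np.inf
    for face in mesh.faces:
        a, b, c = mesh.vertices[face]
        best = min(best, _point_triangle_dist(query, a, b, c))
    return best


def _point_triangle_dist(p, a, b, c) -> float:
    n = np.cross(b - a, c - a)
    nn = np.dot(n, n)
    # project onto plane, check barycentric containment
    t = np.dot(p - a, n) / nn
    proj = p - t * n
    area = np.linalg.norm(n)
    u = np.dot(np.cross(c - b, proj - b), n) / nn
    v = np.dot(np.cross(a - c, proj - c), n) / nn
    w = np.dot(np.cross(b - a, proj - a), n) / nn
    if u >= 0 and v >= 0 and w >= 0 and area > 0:
        return float(np.linalg.norm(p - proj))
    return min(
        _point_segment_dist(p, a, b),
        _point_segment_dist(p, b, c),
        _point_segment_dist(p, c, a),
    )


def _point_segment_dist(p, a, b) -> float:
    d = b - a
    t = np.clip(np.dot(p - a, d) / np.dot(d, d), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * d)))


@pytest.fixture(scope="session")
def small_face():
    return generate_face(
        FaceParams(resolution=TEST_RESOLUTION),
        min_region_vertices=TEST_MIN_REGION_VERTICES,
    )


@pytest.fixture(scope="session")
def null_pair(small_face):
    """Shell/scan pair differing only by decimation."""
    return derive_pair(small_face, PerturbationSpec())


@pytest.fixture(scope="session")
def misaligned_pair(small_face):
    """Noise-free pair with a known rigid misalignment."""
    return derive_pair(
        small_face,
        PerturbationSpec(rotation_deg=(5.0, -5.0, 5.0), translation_mm=(3.0, -2.0, 3.0)),
    )
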