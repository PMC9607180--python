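"""Triangle-mesh data model and geometric primitives.

All coordinates are millimetres in a right-handed frame.  Meshes may be
open (boundary edges are allowed): facial shells are never watertight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Cross-product norm below which a face is considered degenerate (mm^2).
_DEGENERATE_AREA2 = 1e-12

#: Relative tolerance for deciding a closest point sits on an edge/vertex.
_BARY_TOL = 1e-9


class MeshValidationError(ValueError):
    """Raised when mesh vertices/faces violate structural invariants."""


@dataclass
class TriangleMesh:
    """An open triangulated surface in millimetre units.

    Parameters
    ----------
    vertices:
        ``(n, 3)`` float array of vertex positions (mm).
    faces:
        ``(m, 3)`` integer array of vertex indices, counter-clockwise
        winding seen from the outside.
    vertex_scalar:
        Optional ``(n,)`` per-vertex scalar channel (mm), e.g. a deviation
        display value.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_scalar: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")
        if not np.isfinite(self.vertices).all():
            raise MeshValidationError("vertices contain non-finite coordinates")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshValidationError("face index out of range")
        self._drop_degenerate_faces()

    def _drop_degenerate_faces(self) -> None:
        # Segmentation-derived shells commonly contain slivers; drop rather
        # than error, but keep count visible.
        if not len(self.faces):
            return
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.einsum("ij,ij->i", cross, cross)
        combinatorial = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        bad = combinatorial | (area2 <= _DEGENERATE_AREA2)
        if bad.any():
            logger.info("dropped %d degenerate faces", int(bad.sum()))
            self.faces = self.faces[~bad]

    # -- derived quantities, cached per mesh instance ------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @cached_property
    def face_normals(self) -> np.ndarray:
        """Unit normals per face (right-hand rule on the winding)."""
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norms = np.linalg.norm(cross, axis=1, keepdims=True)
        return cross / np.maximum(norms, 1e-300)

    @cached_property
    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @cached_property
    def max_edge_length(self) -> float:
        tri = self.vertices[self.faces]
        e = np.concatenate(
            [tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2]]
        )
        return float(np.sqrt(np.einsum("ij,ij->i", e, e).max())) if len(e) else 0.0

    @cached_property
    def _kdtree(self) -> cKDTree:
        return cKDTree(self.vertices)

    @cached_property
    def _vertex_face_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style (indptr, face_ids) adjacency from vertex to faces."""
        flat = self.faces.ravel()
        order = np.argsort(flat, kind="stable")
        face_ids = order // 3
        counts = np.bincount(flat, minlength=self.n_vertices)
        indptr = np.concatenate([[0], np.cumsum(counts)])
        return indptr, face_ids

    @cached_property
    def _edges_sorted(self) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.sort(e, axis=1)

    @cached_property
    def boundary_edges(self) -> set[tuple[int, int]]:
        """Undirected edges that belong to exactly one face."""
        e = self._edges_sorted
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return {tuple(row) for row in uniq[counts == 1]}

    @cached_property
    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices lying on a boundary edge."""
        mask = np.zeros(self.n_vertices, dtype=bool)
        for i, j in self.boundary_edges:
            mask[i] = True
            mask[j] = True
        return mask

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_scalar is None else self.vertex_scalar.copy(),
            dict(self.extra),
        )

    def transformed(self, transform: "RigidTransform") -> "TriangleMesh":
        return TriangleMesh(
            transform.apply(self.vertices),
            self.faces.copy(),
            None if self.vertex_scalar is None else self.vertex_scalar.copy(),
            dict(self.extra),
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is a reflection (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler_deg(
        cls, angles_deg: tuple[float, float, float], translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Intrinsic x-y-z Euler rotation (degrees) plus a translation (mm)."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
        return cls(R, np.asarray(translation, dtype=np.float64))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_flat(self) -> np.ndarray:
        """Row-major 12-vector: 9 rotation entries then the translation."""
        return np.concatenate([self.rotation.ravel(), self.translation])

    @classmethod
    def from_flat(cls, flat: np.ndarray) -> "RigidTransform":
        flat = np.asarray(flat, dtype=np.float64).reshape(12)
        return cls(flat[:9].reshape(3, 3), flat[9:])


@dataclass(frozen=True)
class ClosestPointResult:
    """Closest point on a target surface for one query point."""

    distance: float
    point: np.ndarray
    face_index: int
    on_boundary: bool


def _closest_on_triangles(p: np.ndarray, a, b, c):
    """Vectorised closest point on triangles (a, b, c) for paired queries p.

    Returns (closest_points, squared_distances).  Region classification
    follows the standard barycentric case analysis.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)  # vertex C

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = d1 / (d1 - d3)
        t_ac = d2 / (d2 - d6)
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t_ab[:, None] * ab)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t_ac[:, None] * ac)
    settle(
        (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0), b + t_bc[:, None] * (c - b)
    )

    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = vb / denom
        w = vc / denom
    interior = a + v[:, None] * ab + w[:, None] * ac
    settle(np.ones(len(p), dtype=bool), interior)

    diff = p - out
    return out, np.einsum("ij,ij->i", diff, diff)


try:  # optional fast path; the numpy implementation is the reference
    from numba import njit as _njit

    @_njit(cache=True)
    def _closest_on_triangles_jit(p, a, b, c, out, d2):  # pragma: no cover
        for i in range(p.shape[0]):
            abx = b[i, 0] - a[i, 0]; aby = b[i, 1] - a[i, 1]; abz = b[i, 2] - a[i, 2]
            acx = c[i, 0] - a[i, 0]; acy = c[i, 1] - a[i, 1]; acz = c[i, 2] - a[i, 2]
            apx = p[i, 0] - a[i, 0]; apy = p[i, 1] - a[i, 1]; apz = p[i, 2] - a[i, 2]
            d1 = abx * apx + aby * apy + abz * apz
            d2_ = acx * apx + acy * apy + acz * apz
            if d1 <= 0.0 and d2_ <= 0.0:
                qx, qy, qz = a[i, 0], a[i, 1], a[i, 2]
            else:
                bpx = p[i, 0] - b[i, 0]; bpy = p[i, 1] - b[i, 1]; bpz = p[i, 2] - b[i, 2]
                d3 = abx * bpx + aby * bpy + abz * bpz
                d4 = acx * bpx + acy * bpy + acz * bpz
                if d3 >= 0.0 and d4 <= d3:
                    qx, qy, qz = b[i, 0], b[i, 1], b[i, 2]
                else:
                    cpx = p[i, 0] - c[i, 0]; cpy = p[i, 1] - c[i, 1]; cpz = p[i, 2] - c[i, 2]
                    d5 = abx * cpx + aby * cpy + abz * cpz
                    d6 = acx * cpx + acy * cpy + acz * cpz
                    if d6 >= 0.0 and d5 <= d6:
                        qx, qy, qz = c[i, 0], c[i, 1], c[i, 2]
                    else:
                        vc = d1 * d4 - d3 * d2_
                        vb = d5 * d2_ - d1 * d6
                        va = d3 * d6 - d5 * d4
                        if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                            t = d1 / (d1 - d3)
                            qx = a[i, 0] + t * abx
                            qy = a[i, 1] + t * aby
                            qz = a[i, 2] + t * abz
                        elif vb <= 0.0 and d2_ >= 0.0 and d6 <= 0.0:
                            t = d2_ / (d2_ - d6)
                            qx = a[i, 0] + t * acx
                            qy = a[i, 1] + t * acy
                            qz = a[i, 2] + t * acz
                        elif va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
                            t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                            qx = b[i, 0] + t * (c[i, 0] - b[i, 0])
                            qy = b[i, 1] + t * (c[i, 1] - b[i, 1])
                            qz = b[i, 2] + t * (c[i, 2] - b[i, 2])
                        else:
                            denom = 1.0 / (va + vb + vc)
                            v = vb * denom
                            w = vc * denom
                            qx = a[i, 0] + abx * v + acx * w
                            qy = a[i, 1] + aby * v + acy * w
                            qz = a[i, 2] + abz * v + acz * w
            out[i, 0] = qx
            out[i, 1] = qy
            out[i, 2] = qz
            dx = p[i, 0] - qx
            dy = p[i, 1] - qy
            dz = p[i, 2] - qz
            d2[i] = dx * dx + dy * dy + dz * dz

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False


def _closest_on_triangles_fast(p, a, b, c):
    """Dispatch to the jitted kernel when available."""
    if _HAVE_NUMBA:
        p = np.ascontiguousarray(p)
        a = np.ascontiguousarray(a)
        b = np.ascontiguousarray(b)
        c = np.ascontiguousarray(c)
        out = np.empty_like(p)
        d2 = np.empty(len(p))
        _closest_on_triangles_jit(p, a, b, c, out, d2)
        return out, d2
    return _closest_on_triangles(p, a, b, c)


def _barycentric(points: np.ndarray, a, b, c) -> np.ndarray:
    """Barycentric coordinates of points known to lie on triangles (a,b,c)."""
    v0 = b - a
    v1 = c - a
    v2 = points - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1e-300, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    return np.stack([1.0 - v - w, v, w], axis=1)


def closest_points(
    queries: np.ndarray, target: TriangleMesh
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Globally minimal point-to-surface distances for a batch of queries.

    Exact: a vertex KD-tree prunes candidate faces with the guarantee that
    any face containing a point closer than the best-so-far upper bound has
    a vertex within ``upper_bound + max_edge_length`` of the query.

    Returns ``(distances, points, face_indices, on_boundary)``.
    """
    if target.n_faces == 0:
        raise MeshValidationError("closest_points requires a non-empty mesh")
    q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    n = len(q)

    ub, _ = target._kdtree.query(q)
    radius = ub + target.max_edge_length + 1e-9
    neighbour_lists = target._kdtree.query_ball_point(q, radius)

    indptr, vert_faces = target._vertex_face_csr

    # Flatten ragged (query, candidate-face) pairs.  A face may appear up
    # to three times per query (once per vertex in the ball); duplicates
    # only cost arithmetic, never correctness.
    counts = np.fromiter((len(v) for v in neighbour_lists), dtype=np.int64, count=n)
    flat_verts = np.fromiter(
        (v for lst in neighbour_lists for v in lst), dtype=np.int64, count=counts.sum()
    )
    vq = np.repeat(np.arange(n), counts)  # query id per candidate vertex
    fcounts = indptr[flat_verts + 1] - indptr[flat_verts]
    # expand CSR slices: positions indptr[v] .. indptr[v]+fcounts[v]-1
    total = int(fcounts.sum())
    offsets = np.repeat(indptr[flat_verts], fcounts)
    ramp = np.arange(total) - np.repeat(
        np.concatenate([[0], np.cumsum(fcounts)[:-1]]), fcounts
    )
    fidx = vert_faces[offsets + ramp]
    qidx = np.repeat(vq, fcounts)

    tri = target.vertices[target.faces[fidx]]
    pts, d2 = _closest_on_triangles_fast(q[qidx], tri[:, 0], tri[:, 1], tri[:, 2])

    best_d2 = np.full(n, np.inf)
    np.minimum.at(best_d2, qidx, d2)
    # winner pair per query (first match at the minimum)
    is_best = d2 <= best_d2[qidx] + 0.0
    # resolve ties deterministically: keep lowest face index among winners
    win_face = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(win_face, qidx[is_best], fidx[is_best])
    sel = is_best & (fidx == win_face[qidx])
    # first occurrence per query among sel
    first = np.full(n, len(qidx), dtype=np.int64)
    rows = np.flatnonzero(sel)
    np.minimum.at(first, qidx[rows], rows)
    first = np.minimum(first, len(qidx) - 1)

    best_pts = pts[first]
    best_faces = fidx[first]
    distances = np.sqrt(best_d2)

    on_boundary = _classify_boundary(target, best_pts, best_faces, distances)
    return distances, best_pts, best_faces, on_boundary


def _classify_boundary(
    target: TriangleMesh,
    points: np.ndarray,
    face_indices: np.ndarray,
    distances: np.ndarray,
) -> np.ndarray:
    """True where a closest point lies on a boundary edge or vertex."""
    faces = target.faces[face_indices]
    tri = target.vertices[faces]
    bary = _barycentric(points, tri[:, 0], tri[:, 1], tri[:, 2])
    scale = np.maximum(1.0, np.abs(bary).max(axis=1))
    zero = np.abs(bary) <= _BARY_TOL * scale[:, None]

    bedges = target.boundary_edges
    bverts = target.boundary_vertices
    out = np.zeros(len(points), dtype=bool)
    n_zero = zero.sum(axis=1)
    for i in range(len(points)):
        if n_zero[i] == 0:
            continue
        f = faces[i]
        if n_zero[i] >= 2:
            # at a vertex: the one with bary ~ 1
            v = f[int(np.argmax(bary[i]))]
            out[i] = bool(bverts[v])
        else:
            k = int(np.flatnonzero(zero[i])[0])  # opposite vertex index
            edge = tuple(sorted((int(f[(k + 1) % 3]), int(f[(k + 2) % 3]))))
            out[i] = edge in bedges
    return out


def closest_point(query: np.ndarray, target: TriangleMesh) -> ClosestPointResult:
    """Closest point on ``target`` for a single query point."""
    d, p, f, b = closest_points(np.asarray(query, dtype=np.float64)[None, :], target)
    return ClosestPointResult(
        distance=float(d[0]),
        point=p[0],
        face_index=int(f[0]),
        on_boundary=bool(b[0]),
    )


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted per-vertex unit normals.

    Isolated vertices get a zero vector (flagged for downstream exclusion
    rather than NaN).
    """
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2*area*n
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], cross)
    norms = np.linalg.norm(acc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 1e-300, acc / np.maximum(norms, 1e-300), 0.0)
    return out
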