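"""STL (binary + ASCII) read/write and ASCII PLY export.

STL stores facets independently; on read, vertices closer than the merge
tolerance are welded so faces share vertices and connectivity queries
(boundary edges, vertex normals) become meaningful.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Optional, Union

import numpy as np

from facedev.mesh_core.geometry import TriangleMesh

#: Weld tolerance on read (mm) — far below any sensor precision.
MERGE_TOL = 1e-6

_BINARY_HEADER = b"facedev binary STL"

_FACET_DTYPE = np.dtype(
    [
        ("normal", "<f4", (3,)),
        ("v0", "<f4", (3,)),
        ("v1", "<f4", (3,)),
        ("v2", "<f4", (3,)),
        ("attr", "<u2"),
    ]
)


class StlParseError(ValueError):
    """Malformed or truncated STL content; message names the offset."""


def _weld(triangles: np.ndarray, tol: float = MERGE_TOL) -> TriangleMesh:
    """Merge duplicate corner vertices within ``tol`` and build a mesh."""
    flat = triangles.reshape(-1, 3).astype(np.float64)
    key = np.round(flat / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    vertices = flat[first]
    faces = inverse.reshape(-1, 3)
    return TriangleMesh(vertices, faces)


def _read_stl_binary(raw: bytes, path: Union[str, Path]) -> TriangleMesh:
    if len(raw) < 84:
        raise StlParseError(
            f"{path}: binary STL truncated at byte {len(raw)} (header needs 84)"
        )
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * count
    if len(raw) < expected:
        raise StlParseError(
            f"{path}: binary STL truncated at byte {len(raw)}, "
            f"expected {expected} for {count} facets"
        )
    facets = np.frombuffer(raw, dtype=_FACET_DTYPE, count=count, offset=84)
    tris = np.stack([facets["v0"], facets["v1"], facets["v2"]], axis=1)
    return _weld(tris)


def _read_stl_ascii(text: str, path: Union[str, Path]) -> TriangleMesh:
    tris: list[list[float]] = []
    current: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        kw = parts[0].lower()
        if kw == "vertex":
            if len(parts) != 4:
                raise StlParseError(f"{path}: line {lineno}: malformed vertex line")
            try:
                current.extend(float(p) for p in parts[1:])
            except ValueError as exc:
                raise StlParseError(
                    f"{path}: line {lineno}: non-numeric vertex coordinate"
                ) from exc
        elif kw == "endfacet":
            if len(current) != 9:
                raise StlParseError(
                    f"{path}: line {lineno}: facet has {len(current) // 3} vertices"
                )
            tris.append(current)
            current = []
        elif kw not in {
            "solid",
            "endsolid",
            "facet",
            "outer",
            "endloop",
        }:
            raise StlParseError(f"{path}: line {lineno}: unexpected token {kw!r}")
    if current:
        raise StlParseError(f"{path}: unterminated facet at end of file")
    if not tris:
        raise StlParseError(f"{path}: ASCII STL contains no facets")
    return _weld(np.asarray(tris, dtype=np.float64).reshape(-1, 3, 3))


def read_stl(path: Union[str, Path]) -> TriangleMesh:
    """Read a binary or ASCII STL file, auto-detecting the dialect."""
    raw = Path(path).read_bytes()
    if len(raw) >= 84:
        (count,) = struct.unpack_from("<I", raw, 80)
        if len(raw) == 84 + 50 * count and not raw.lstrip()[:5] == b"solid":
            return _read_stl_binary(raw, path)
        if len(raw) == 84 + 50 * count and raw.lstrip()[:5] == b"solid":
            # Ambiguous: "solid" header with exact binary size. Prefer ASCII
            # if it parses, else fall back to binary.
            try:
                return _read_stl_ascii(raw.decode("ascii", errors="strict"), path)
            except (StlParseError, UnicodeDecodeError):
                return _read_stl_binary(raw, path)
    if raw.lstrip()[:5] == b"solid":
        try:
            text = raw.decode("ascii")
        except UnicodeDecodeError:
            return _read_stl_binary(raw, path)
        return _read_stl_ascii(text, path)
    return _read_stl_binary(raw, path)


def _facet_normals(mesh: TriangleMesh) -> np.ndarray:
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(cross, axis=1, keepdims=True)
    return np.where(norms > 1e-300, cross / np.maximum(norms, 1e-300), 0.0)


def write_stl(
    mesh: TriangleMesh, path: Union[str, Path], dialect: str = "binary"
) -> None:
    """Write a mesh as STL; output is bit-stable for a fixed input.

    Normals are recomputed from the vertex winding; binary attribute bytes
    are zero (STL has no portable colour).
    """
    if mesh.n_faces == 0:
        raise ValueError("refusing to write an empty mesh (no faces)")
    if dialect not in {"binary", "ascii"}:
        raise ValueError(f"unknown STL dialect {dialect!r}")
    normals = _facet_normals(mesh)
    tri = mesh.vertices[mesh.faces]
    path = Path(path)
    if dialect == "binary":
        facets = np.zeros(mesh.n_faces, dtype=_FACET_DTYPE)
        facets["normal"] = normals.astype("<f4")
        facets["v0"] = tri[:, 0].astype("<f4")
        facets["v1"] = tri[:, 1].astype("<f4")
        facets["v2"] = tri[:, 2].astype("<f4")
        header = _BINARY_HEADER.ljust(80, b"\0")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", mesh.n_faces))
            fh.write(facets.tobytes())
    else:
        lines = ["solid facedev"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid facedev")
        path.write_text("\n".join(lines) + "\n")


def write_ply(
    mesh: TriangleMesh,
    path: Union[str, Path],
    quality: Optional[np.ndarray] = None,
    colors: Optional[np.ndarray] = None,
) -> None:
    """Write an ASCII PLY with optional per-vertex quality and RGB colour."""
    path = Path(path)
    n = mesh.n_vertices
    if quality is not None and len(quality) != n:
        raise ValueError("quality length must match vertex count")
    if colors is not None and len(colors) != n:
        raise ValueError("colors length must match vertex count")
    header = [
        "ply",
        "format ascii 1.0",
        "comment facedev deviation heatmap",
        f"element vertex {n}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if quality is not None:
        header.append("property float quality")
    if colors is not None:
        header += [
            "property uchar red",
            "property uchar green",
            "property uchar blue",
        ]
    header += [f"element face {mesh.n_faces}", "property list uchar int vertex_indices", "end_header"]

    lines = header
    for i in range(n):
        v = mesh.vertices[i]
        row = f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}"
        if quality is not None:
            row += f" {float(quality[i]):.6f}"
        if colors is not None:
            c = colors[i]
            row += f" {int(c[0])} {int(c[1])} {int(c[2])}"
        lines.append(row)
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")
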