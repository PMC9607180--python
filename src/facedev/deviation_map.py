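"""Absolute surface-deviation fields and heatmap export.

Sign is deliberately discarded: the field stores the absolute distance
from each (aligned) scan vertex to the reference shell surface.  A display
cap (default 3 mm) mirrors the clinical colormap limit; classification
always uses the raw, uncapped value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from facedev.mesh_core import TriangleMesh, closest_points, write_ply

DEFAULT_CAP_MM = 3.0
#: Distances beyond this are treated as non-overlap (crop artifacts), not
#: true soft-tissue deviation.
DEFAULT_MAX_VALID_MM = 10.0


@dataclass
class DeviationField:
    """Per-scan-vertex absolute deviation from the reference shell."""

    raw: np.ndarray  # absolute distance, mm
    display: np.ndarray  # min(raw, cap); NaN where invalid
    valid: np.ndarray  # bool
    cap: float

    def __post_init__(self) -> None:
        if not (len(self.raw) == len(self.display) == len(self.valid)):
            raise ValueError("field arrays must share one length")


def absolute_deviation(
    scan_aligned: TriangleMesh,
    shell: TriangleMesh,
    cap: float = DEFAULT_CAP_MM,
    max_valid: float = DEFAULT_MAX_VALID_MM,
) -> DeviationField:
    """Measure each scan vertex against the shell surface.

    Vertices whose closest shell point lies on a boundary edge, or whose
    distance exceeds ``max_valid``, are marked invalid: they indicate
    missing shell coverage rather than real deviation.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if shell.n_faces == 0:
        raise ValueError("reference shell has no faces")
    raw, _, _, on_boundary = closest_points(scan_aligned.vertices, shell)
    valid = ~on_boundary & (raw <= max_valid)
    display = np.minimum(raw, cap)
    display = np.where(valid, display, np.nan)
    return DeviationField(raw=raw, display=display, valid=valid, cap=cap)


def heatmap_colors(field: DeviationField) -> np.ndarray:
    """White-to-red linear ramp over [0, cap]; invalid vertices gray."""
    t = np.clip(np.nan_to_num(field.display, nan=0.0) / field.cap, 0.0, 1.0)
    colors = np.empty((len(t), 3), dtype=np.uint8)
    colors[:, 0] = 255
    gb = np.rint(255 * (1.0 - t)).astype(np.uint8)
    colors[:, 1] = gb
    colors[:, 2] = gb
    colors[~field.valid] = (128, 128, 128)
    return colors


def export_heatmap(
    field: DeviationField,
    scan_aligned: TriangleMesh,
    path_prefix: Union[str, Path],
) -> tuple[Path, Path]:
    """Write ``<prefix>.ply`` (colored, quality channel) and ``<prefix>.csv``."""
    if len(field.raw) != scan_aligned.n_vertices:
        raise ValueError("field length does not match scan vertex count")
    prefix = Path(path_prefix)
    ply_path = prefix.with_suffix(".ply")
    csv_path = prefix.with_suffix(".csv")
    quality = np.where(field.valid, np.nan_to_num(field.display, nan=0.0), -1.0)
    write_ply(scan_aligned, ply_path, quality=quality, colors=heatmap_colors(field))
    pd.DataFrame(
        {
            "vertex_id": np.arange(len(field.raw)),
            "raw_mm": field.raw,
            "display_mm": field.display,
            "valid": field.valid,
        }
    ).to_csv(csv_path, index=False)
    return ply_path, csv_path


def _chain_segments(segments: np.ndarray, tol: float = 1e-9) -> list[np.ndarray]:
    """Chain unordered 3D segments into ordered polylines."""
    if not len(segments):
        return []
    key = np.round(segments.reshape(-1, 3) / tol).astype(np.int64)
    _, inverse = np.unique(key, axis=0, return_inverse=True)
    ends = inverse.reshape(-1, 2)  # node ids per segment
    points: dict[int, np.ndarray] = {}
    adj: dict[int, list[tuple[int, int]]] = {}
    for si, (a, b) in enumerate(ends):
        points[int(a)] = segments[si, 0]
        points[int(b)] = segments[si, 1]
        adj.setdefault(int(a), []).append((int(b), si))
        adj.setdefault(int(b), []).append((int(a), si))
    used = np.zeros(len(segments), dtype=bool)
    polylines: list[np.ndarray] = []
    # open chains first (start at odd-degree nodes), then closed loops
    starts = [n for n, nb in adj.items() if len(nb) % 2 == 1] + list(adj)
    for start in starts:
        path = [start]
        node = start
        while True:
            nxt = next(((m, si) for m, si in adj[node] if not used[si]), None)
            if nxt is None:
                break
            m, si = nxt
            used[si] = True
            path.append(m)
            node = m
        if len(path) > 1:
            polylines.append(np.array([points[n] for n in path]))
    return polylines


def cross_section(
    mesh: TriangleMesh, plane_point: np.ndarray, plane_normal: np.ndarray
) -> list[np.ndarray]:
    """Intersect a mesh with a plane; returns ordered polylines.

    Vertices exactly on the plane are nudged by a tiny epsilon so every
    crossing face yields exactly one segment.
    """
    n = np.asarray(plane_normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    p0 = np.asarray(plane_point, dtype=np.float64)
    s = (mesh.vertices - p0) @ n
    s = np.where(s == 0.0, 1e-12, s)
    sf = s[mesh.faces]
    crossing = ~((sf > 0).all(axis=1) | (sf < 0).all(axis=1))
    segs = []
    for f, sv in zip(mesh.faces[crossing], sf[crossing]):
        pts = []
        for i, j in ((0, 1), (1, 2), (2, 0)):
            if sv[i] * sv[j] < 0:
                t = sv[i] / (sv[i] - sv[j])
                pts.append(mesh.vertices[f[i]] + t * (mesh.vertices[f[j]] - mesh.vertices[f[i]]))
        if len(pts) == 2 and np.linalg.norm(pts[1] - pts[0]) > 1e-9:
            segs.append(pts)
    if not segs:
        return []
    lines = _chain_segments(np.asarray(segs))
    # drop zero-length fragments from vertices sitting exactly on the plane
    return [
        ln
        for ln in lines
        if np.linalg.norm(np.diff(ln, axis=0), axis=1).sum() > 1e-6
    ]


def profile_section(
    shell: TriangleMesh,
    scan_aligned: TriangleMesh,
    plane_point=(0.0, 0.0, 0.0),
    plane_normal=(1.0, 0.0, 0.0),
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Sagittal (by default) section polylines of both meshes.

    Used to cross-check the heatmap numerically in the median plane.
    Returns ``(shell_polylines, scan_polylines)``; empty lists with a
    warning when the plane misses a mesh.
    """
    import warnings

    shell_lines = cross_section(shell, plane_point, plane_normal)
    scan_lines = cross_section(scan_aligned, plane_point, plane_normal)
    if not shell_lines or not scan_lines:
        warnings.warn("section plane misses at least one mesh", stacklevel=2)
    return shell_lines, scan_lines


def polyline_to_csv(polylines: list[np.ndarray], path: Union[str, Path]) -> None:
    rows = []
    for pid, line in enumerate(polylines):
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(line, axis=0), axis=1))]
        )
        for (x, y, z), a in zip(line, arc):
            rows.append({"polyline": pid, "arc_mm": a, "x": x, "y": y, "z": z})
    pd.DataFrame(rows).to_csv(path, index=False)
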