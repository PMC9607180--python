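"""Synthetic paired facial meshes with known ground truth.

The face is a parametric composition of Gaussian bumps and depressions on
an ellipsoidal base — not anatomically realistic, but it hosts every named
facial region with a controllable convexity class, which is what the
downstream analysis actually depends on.

From one generated face, :func:`derive_pair` produces
  * a high-resolution reference shell (optionally forehead-cropped, with
    closed eyelids), and
  * a lower-resolution scan (~4:1 face-count ratio) with per-region
    normal-direction offsets, concavity-dependent depth noise, an optional
    open-eyelid mismatch, and a known rigid misalignment,
together with a :class:`GroundTruth` recording exactly what was injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from facedev.mesh_core import RigidTransform, TriangleMesh, vertex_normals
from facedev.regional_analysis import RegionAtlas

#: All named facial regions, in atlas priority order (specific first).
FACIAL_REGIONS: tuple[str, ...] = (
    "apex of nose",
    "ala nasi L",
    "ala nasi R",
    "nasal bridge L",
    "nasal bridge R",
    "sulcus nasolabialis L",
    "sulcus nasolabialis R",
    "philtrum",
    "vermilion border",
    "vermilion",
    "oral/labial commisure L",
    "oral/labial commisure R",
    "oral fissure",
    "sulcus mentolabialis",
    "mental region",
    "orbital region L",
    "orbital region R",
    "infraorbital region",
    "zygomatic region",
    "temporal region",
    "frontal region",
    "parotid-masseteric region",
    "buccal region",
)

#: The seven sites visible from the lateral view, midline top to bottom.
LATERAL_SITES: tuple[str, ...] = (
    "frontal region",
    "apex of nose",
    "philtrum",
    "vermilion border",
    "oral fissure",
    "sulcus mentolabialis",
    "mental region",
)

#: Concave regions of the generator (hollows/grooves), for noise scaling.
CONCAVE_REGIONS = frozenset(
    {
        "orbital region L",
        "orbital region R",
        "sulcus mentolabialis",
        "sulcus nasolabialis L",
        "sulcus nasolabialis R",
        "temporal region",
        "oral fissure",
    }
)

#: Offsets beyond this would fold regions into their neighbours.
MAX_OFFSET_MM = 15.0


@dataclass(frozen=True)
class FaceParams:
    """Global size and feature amplitudes of a synthetic face (mm)."""

    head_width: float = 140.0
    head_height: float = 180.0
    head_depth: float = 95.0
    nose_amplitude: float = 22.0
    lip_amplitude: float = 4.0
    chin_amplitude: float = 8.0
    brow_amplitude: float = 5.0
    eye_socket_depth: float = 4.0
    eyelids: str = "closed"  # "closed" (CBCT-like) or "open"
    resolution: int = 128  # vertices per axis
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "head_width",
            "head_height",
            "head_depth",
            "nose_amplitude",
            "lip_amplitude",
            "chin_amplitude",
            "brow_amplitude",
            "eye_socket_depth",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.resolution < 30:
            raise ValueError("resolution must be at least 30 vertices per axis")
        if self.eyelids not in {"closed", "open"}:
            raise ValueError("eyelids must be 'closed' or 'open'")


@dataclass(frozen=True)
class PerturbationSpec:
    """What to inject into the scan (and shell) of a derived pair."""

    #: region name -> (normal offset amplitude mm, extra noise sd mm)
    region_offsets: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    forehead_crop: float = 0.0
    eyelid_mismatch: bool = False
    concavity_gain: float = 0.0
    base_noise_sd: float = 0.0
    decimation_step: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for region, (amp, sd) in self.region_offsets.items():
            if amp < 0 or sd < 0:
                raise ValueError(f"negative amplitude/sd for region {region!r}")
        if not 0.0 <= self.forehead_crop < 1.0:
            raise ValueError("forehead_crop must be in [0, 1)")
        if self.decimation_step < 1:
            raise ValueError("decimation_step must be >= 1")


@dataclass
class GroundTruth:
    """Exactly what was injected into a derived pair."""

    region_deviation_mm: dict[str, float]
    transform: RigidTransform
    artifacts: dict

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {
                "region": list(self.region_deviation_mm),
                "deviation_mm": list(self.region_deviation_mm.values()),
            }
        ).to_csv(path, index=False)


@dataclass
class SyntheticFace:
    """A generated face plus its landmarks, atlas, and provenance."""

    mesh: TriangleMesh
    landmarks: dict[str, np.ndarray]
    atlas: RegionAtlas
    params: FaceParams
    grid_shape: tuple[int, int]


@dataclass
class MeshPair:
    """Reference shell / scan pair with full bookkeeping."""

    shell: TriangleMesh
    shell_atlas: RegionAtlas
    shell_landmarks: dict[str, np.ndarray]
    scan: TriangleMesh
    scan_atlas: RegionAtlas
    scan_landmarks: dict[str, np.ndarray]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# height field and atlas layout (x lateral, +x = subject's left; y vertical,
# up; z out of the face; origin near the nose)


def _height_field(params: FaceParams, eyelids: str) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    W, H, D = params.head_width, params.head_height, params.head_depth
    a, b = 0.55 * W, 0.55 * H

    def g(x, y, cx, cy, sx, sy):
        return np.exp(-((x - cx) ** 2 / (2 * sx**2) + (y - cy) ** 2 / (2 * sy**2)))

    def gm(x, y, cx, cy, sx, sy):  # mirrored in x
        return np.exp(
            -((np.abs(x) - cx) ** 2 / (2 * sx**2) + (y - cy) ** 2 / (2 * sy**2))
        )

    lid = 1.2 if eyelids == "closed" else -1.2

    def f(x, y):
        # paraboloid dome rather than a true ellipsoid cap: bounded slope
        # everywhere keeps triangle edges short near the open boundary
        z = D * np.clip(1.0 - (x / a) ** 2 - (y / b) ** 2, 0.0, None)
        z = z + params.nose_amplitude * g(x, y, 0, 4, 8, 14)  # nasal ridge
        z = z + 0.5 * params.nose_amplitude * g(x, y, 0, 0, 6, 6)  # pronasale
        z = z + params.brow_amplitude * g(x, y, 0, 32, 28, 5)  # brow
        z = z + params.lip_amplitude * g(x, y, 0, -24, 16, 4)  # vermilion
        z = z + params.chin_amplitude * g(x, y, 0, -43, 11, 8)  # mental
        z = z - params.eye_socket_depth * gm(x, y, 21, 24, 7, 5)  # orbits
        z = z - 3.0 * gm(x, y, 51, 42, 8, 11)  # temporal hollows
        z = z - 2.5 * g(x, y, 0, -31, 9, 3)  # mentolabial groove
        z = z - 2.0 * gm(x, y, 16, -9, 4, 6)  # nasolabial grooves
        z = z - 1.5 * g(x, y, 0, -28, 16, 2)  # oral fissure
        z = z + lid * gm(x, y, 21, 24, 4, 3)  # eyelid state
        return z

    return f


def _region_masks(x: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    """Boolean vertex masks per region; priority order keeps them disjoint."""
    ax = np.abs(x)
    L = x > 0
    R = x < 0
    boxes: dict[str, np.ndarray] = {
        "apex of nose": (ax <= 7) & (y > -4) & (y <= 8),
        "ala nasi L": L & (ax > 7) & (ax <= 17) & (y > -9) & (y <= 7),
        "ala nasi R": R & (ax > 7) & (ax <= 17) & (y > -9) & (y <= 7),
        "nasal bridge L": L & (ax <= 9) & (y > 8) & (y <= 30),
        "nasal bridge R": R & (ax <= 9) & (y > 8) & (y <= 30),
        "sulcus nasolabialis L": L & (ax > 12) & (ax <= 23) & (y > -17) & (y <= -3),
        "sulcus nasolabialis R": R & (ax > 12) & (ax <= 23) & (y > -17) & (y <= -3),
        "philtrum": (ax <= 8) & (y > -18) & (y <= -8),
        "vermilion border": (ax <= 20) & (y > -22) & (y <= -18),
        "vermilion": (ax <= 20) & (y > -26) & (y <= -22),
        "oral/labial commisure L": L & (ax > 20) & (ax <= 31) & (y > -32) & (y <= -17),
        "oral/labial commisure R": R & (ax > 20) & (ax <= 31) & (y > -32) & (y <= -17),
        "oral fissure": (ax <= 20) & (y > -30) & (y <= -26),
        "sulcus mentolabialis": (ax <= 14) & (y > -36) & (y <= -30),
        "mental region": (ax <= 16) & (y > -52) & (y <= -36),
        "orbital region L": L & (ax > 12) & (ax <= 32) & (y > 18) & (y <= 30),
        "orbital region R": R & (ax > 12) & (ax <= 32) & (y > 18) & (y <= 30),
        "infraorbital region": (ax > 10) & (ax <= 32) & (y > 8) & (y <= 18),
        "zygomatic region": (ax > 32) & (ax <= 52) & (y > 2) & (y <= 18),
        "temporal region": (ax > 40) & (ax <= 62) & (y > 28) & (y <= 58),
        "frontal region": (ax <= 35) & (y > 32) & (y <= 75),
        "parotid-masseteric region": (ax > 38) & (ax <= 60) & (y > -32) & (y <= -8),
        "buccal region": (ax > 22) & (ax <= 38) & (y > -16) & (y <= 0),
    }
    claimed = np.zeros(len(x), dtype=bool)
    out: dict[str, np.ndarray] = {}
    for name in FACIAL_REGIONS:
        m = boxes[name] & ~claimed
        out[name] = m
        claimed |= m
    return out


_LANDMARK_XY = {
    "glabella": (0.0, 33.0),
    "temple L": (52.0, 43.0),
    "temple R": (-52.0, 43.0),
    "pronasale": (0.0, 2.0),
    "zygion L": (44.0, 8.0),
    "zygion R": (-44.0, 8.0),
}


def _grid_faces(n_rows: int, n_cols: int) -> np.ndarray:
    """Triangulate a grid (rows advance along x, columns along y).

    Winding is chosen so face normals point toward +z (out of the face).
    """
    i, j = np.meshgrid(np.arange(n_rows - 1), np.arange(n_cols - 1), indexing="ij")
    v00 = (i * n_cols + j).ravel()
    v01 = v00 + 1
    v10 = v00 + n_cols
    v11 = v10 + 1
    f1 = np.stack([v00, v11, v01], axis=1)
    f2 = np.stack([v00, v10, v11], axis=1)
    return np.concatenate([f1, f2])


def generate_face(
    params: FaceParams, min_region_vertices: int = 20
) -> SyntheticFace:
    """Deterministically generate a face mesh, landmarks and region atlas.

    Raises if the resolution is too low for every region to receive at
    least ``min_region_vertices`` vertices.
    """
    n = params.resolution
    xs = np.linspace(-params.head_width / 2, params.head_width / 2, n)
    ys = np.linspace(-params.head_height / 2, params.head_height / 2, n)
    X, Y = np.meshgrid(xs, ys, indexing="ij")  # row i: x, col j: y
    x = X.ravel()
    y = Y.ravel()
    f = _height_field(params, params.eyelids)
    z = f(x, y)
    vertices = np.stack([x, y, z], axis=1)
    faces = _grid_faces(n, n)
    mesh = TriangleMesh(vertices, faces, extra={"grid_shape": (n, n)})

    masks = _region_masks(x, y)
    labels = np.full(len(x), "", dtype=object)
    for name, m in masks.items():
        count = int(m.sum())
        if count < min_region_vertices:
            raise ValueError(
                f"resolution {n} gives region {name!r} only {count} vertices "
                f"(need >= {min_region_vertices})"
            )
        labels[m] = name
    atlas = RegionAtlas(labels)

    landmarks = {
        name: np.array([lx, ly, float(f(np.array([lx]), np.array([ly]))[0])])
        for name, (lx, ly) in _LANDMARK_XY.items()
    }
    return SyntheticFace(mesh, landmarks, atlas, params, (n, n))


def _grid_laplacian(z: np.ndarray) -> np.ndarray:
    """Neighbour-mean minus centre on a grid; positive in concavities (mm)."""
    lap = np.zeros_like(z)
    inner = (z[:-2, 1:-1] + z[2:, 1:-1] + z[1:-1, :-2] + z[1:-1, 2:]) / 4.0 - z[
        1:-1, 1:-1
    ]
    lap[1:-1, 1:-1] = inner
    return lap


def derive_pair(face: SyntheticFace, spec: PerturbationSpec) -> MeshPair:
    """Derive a (reference shell, scan, ground truth) triple from a face."""
    unknown = set(spec.region_offsets) - set(FACIAL_REGIONS)
    if unknown:
        raise ValueError(f"unknown region(s) in offsets: {sorted(unknown)}")
    for region, (amp, _) in spec.region_offsets.items():
        if amp > MAX_OFFSET_MM:
            raise ValueError(
                f"offset {amp} mm for {region!r} exceeds {MAX_OFFSET_MM} mm; "
                "regions would self-intersect"
            )
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols = face.grid_shape
    step = spec.decimation_step

    # ---- scan: decimated subgrid ------------------------------------
    ii = np.arange(0, n_rows, step)
    jj = np.arange(0, n_cols, step)
    sub = (ii[:, None] * n_cols + jj[None, :]).ravel()
    scan_vertices = face.mesh.vertices[sub].copy()
    scan_faces = _grid_faces(len(ii), len(jj))
    scan_labels = face.atlas.labels[sub].copy()
    normals = vertex_normals(face.mesh)[sub]

    if spec.eyelid_mismatch:
        f_closed = _height_field(face.params, face.params.eyelids)
        flipped = "open" if face.params.eyelids == "closed" else "closed"
        f_open = _height_field(face.params, flipped)
        xq, yq = scan_vertices[:, 0], scan_vertices[:, 1]
        scan_vertices[:, 2] += f_open(xq, yq) - f_closed(xq, yq)

    truth_dev = {name: 0.0 for name in FACIAL_REGIONS}
    for region, (amp, sd) in spec.region_offsets.items():
        m = scan_labels == region
        offsets = amp + (rng.standard_normal(int(m.sum())) * sd if sd > 0 else 0.0)
        scan_vertices[m] += np.atleast_1d(offsets)[:, None] * normals[m]
        truth_dev[region] = float(amp)

    if spec.base_noise_sd > 0 or spec.concavity_gain > 0:
        zgrid = face.mesh.vertices[:, 2].reshape(n_rows, n_cols)[
            np.ix_(ii, jj)
        ]
        concavity = np.clip(_grid_laplacian(zgrid).ravel(), 0.0, None)
        sd_per_vertex = spec.base_noise_sd + spec.concavity_gain * concavity
        noise = rng.standard_normal(len(scan_vertices)) * sd_per_vertex
        scan_vertices += noise[:, None] * normals

    transform = RigidTransform.from_euler_deg(spec.rotation_deg, spec.translation_mm)
    scan_vertices = transform.apply(scan_vertices)
    scan = TriangleMesh(
        scan_vertices, scan_faces, extra={"grid_shape": (len(ii), len(jj))}
    )
    scan_landmarks = {k: transform.apply(v) for k, v in face.landmarks.items()}

    # ---- reference shell: full resolution, optional forehead crop ----
    shell = face.mesh.copy()
    shell_labels = face.atlas.labels.copy()
    cropped = 0
    if spec.forehead_crop > 0:
        frontal = shell_labels == "frontal region"
        yf = shell.vertices[frontal, 1]
        y_cut = yf.max() - spec.forehead_crop * (yf.max() - yf.min())
        keep = shell.vertices[:, 1] <= y_cut
        cropped = int((~keep).sum())
        remap = -np.ones(shell.n_vertices, dtype=np.int64)
        remap[keep] = np.arange(int(keep.sum()))
        fkeep = keep[shell.faces].all(axis=1)
        shell = TriangleMesh(shell.vertices[keep], remap[shell.faces[fkeep]])
        shell_labels = shell_labels[keep]

    truth = GroundTruth(
        region_deviation_mm=truth_dev,
        transform=transform,
        artifacts={
            "forehead_crop": spec.forehead_crop,
            "cropped_vertices": cropped,
            "eyelid_mismatch": spec.eyelid_mismatch,
            "concavity_gain": spec.concavity_gain,
            "base_noise_sd": spec.base_noise_sd,
        },
    )
    return MeshPair(
        shell=shell,
        shell_atlas=RegionAtlas(shell_labels),
        shell_landmarks=dict(face.landmarks),
        scan=scan,
        scan_atlas=RegionAtlas(scan_labels),
        scan_landmarks=scan_landmarks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class DeviationProfile:
    """Per-region defect model for cohort simulation.

    ``region_probs`` maps a region to the Bernoulli probability of a
    clinically relevant (>3 mm) defect, either one float or a
    ``(p_men, p_women)`` pair.  Defect amplitudes are drawn uniformly from
    ``defect_amplitude_mm``; non-defect regions get no offset.
    """

    region_probs: Mapping[str, Union[float, tuple[float, float]]] = field(
        default_factory=dict
    )
    defect_amplitude_mm: tuple[float, float] = (4.0, 6.0)
    defect_noise_sd: float = 0.2
    base_noise_sd: float = 0.15
    concavity_gain: float = 0.5
    misalign_rot_deg: float = 5.0
    misalign_trans_mm: float = 5.0
    forehead_crop: float = 0.0
    eyelid_mismatch: bool = False
    interval_days_range: tuple[int, int] = (0, 10)
    p_expression_ok: float = 1.0
    p_artifact_ok: float = 1.0
    resolution: int = 128

    def prob_for(self, region: str, sex: str) -> float:
        p = self.region_probs.get(region, 0.0)
        if isinstance(p, tuple):
            return p[0] if sex == "M" else p[1]
        return float(p)


@dataclass
class SubjectCase:
    """One simulated subject; meshes are realised lazily."""

    subject_id: str
    sex: str
    interval_days: int
    expression_ok: bool
    artifact_ok: bool
    params: FaceParams
    spec: PerturbationSpec
    _pair: Optional[MeshPair] = field(default=None, repr=False)
    _face: Optional[SyntheticFace] = field(default=None, repr=False)

    def realize(self, min_region_vertices: int = 20) -> MeshPair:
        if self._pair is None:
            self._face = generate_face(self.params, min_region_vertices)
            self._pair = derive_pair(self._face, self.spec)
        return self._pair


def simulate_cohort(
    n_men: int = 19,
    n_women: int = 41,
    profile: Optional[DeviationProfile] = None,
    seed: int = 0,
) -> list[SubjectCase]:
    """Simulate a reproducible cohort of paired-scan subjects.

    Each subject gets an independent substream derived from
    ``(seed, subject index)``, so changing the cohort size does not
    reshuffle existing subjects.
    """
    if n_men + n_women < 1:
        raise ValueError("cohort must contain at least one subject")
    profile = profile or DeviationProfile()
    cases: list[SubjectCase] = []
    sexes = ["M"] * n_men + ["F"] * n_women
    for idx, sex in enumerate(sexes):
        rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
        scale = rng.uniform(0.95, 1.05, size=3)
        params = FaceParams(
            head_width=140.0 * scale[0],
            head_height=180.0 * scale[1],
            head_depth=95.0 * scale[2],
            resolution=profile.resolution,
            seed=seed,
        )
        offsets: dict[str, tuple[float, float]] = {}
        for region in FACIAL_REGIONS:
            p = profile.prob_for(region, sex)
            if p > 0 and rng.random() < p:
                amp = rng.uniform(*profile.defect_amplitude_mm)
                offsets[region] = (float(amp), profile.defect_noise_sd)
        rot = tuple(rng.uniform(-profile.misalign_rot_deg, profile.misalign_rot_deg, 3))
        trans = tuple(
            rng.uniform(-profile.misalign_trans_mm, profile.misalign_trans_mm, 3)
        )
        spec = PerturbationSpec(
            region_offsets=offsets,
            rotation_deg=rot,
            translation_mm=trans,
            forehead_crop=profile.forehead_crop,
            eyelid_mismatch=profile.eyelid_mismatch,
            concavity_gain=profile.concavity_gain,
            base_noise_sd=profile.base_noise_sd,
            seed=int(rng.integers(0, 2**31)),
        )
        lo, hi = profile.interval_days_range
        cases.append(
            SubjectCase(
                subject_id=f"S{idx:03d}",
                sex=sex,
                interval_days=int(rng.integers(lo, hi + 1)),
                expression_ok=bool(rng.random() < profile.p_expression_ok),
                artifact_ok=bool(rng.random() < profile.p_artifact_ok),
                params=params,
                spec=spec,
            )
        )
    return cases


def cohort_manifest(cases: list[SubjectCase]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in cases],
            "sex": [c.sex for c in cases],
            "interval_days": [c.interval_days for c in cases],
            "expression_ok": [c.expression_ok for c in cases],
            "artifact_ok": [c.artifact_ok for c in cases],
        }
    )


def write_case_bundle(
    case: SubjectCase, directory: Union[str, Path], min_region_vertices: int = 20
) -> Path:
    """Write shell.stl, scan.stl, landmarks, atlas and truth for one subject."""
    import json

    from scipy.spatial import cKDTree

    from facedev.mesh_core import read_stl, write_stl

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pair = case.realize(min_region_vertices)
    write_stl(pair.shell, directory / "shell.stl")
    write_stl(pair.scan, directory / "scan.stl")
    landmarks = {
        "shell": {k: list(map(float, v)) for k, v in pair.shell_landmarks.items()},
        "scan": {k: list(map(float, v)) for k, v in pair.scan_landmarks.items()},
    }
    (directory / "landmarks.json").write_text(json.dumps(landmarks, indent=1))
    # STL reading welds and may reorder vertices: write the atlas in the
    # vertex order a reader of scan.stl will actually see
    reread = read_stl(directory / "scan.stl")
    dist, src_idx = cKDTree(pair.scan.vertices).query(reread.vertices)
    if len(reread.vertices) != pair.scan.n_vertices or dist.max() > 1e-3:
        raise RuntimeError("scan.stl round-trip did not preserve vertices")
    RegionAtlas(pair.scan_atlas.labels[src_idx]).to_csv(directory / "atlas.csv")
    pair.truth.to_csv(directory / "truth.csv")
    return directory
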