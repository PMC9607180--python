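"""Two-stage rigid superimposition of a scan onto a reference shell.

Coarse alignment comes from a closed-form least-squares fit on
expression-stable landmarks (forehead/temples/nose/cheekbones); fine
alignment is trimmed point-to-point ICP restricted to expression-stable
regions of the atlas.  Correspondences landing on a boundary edge of the
open shell are rejected (edge suction guard); the worst 10% by distance
are trimmed to resist crop artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from facedev.deviation_map import absolute_deviation
from facedev.mesh_core import RigidTransform, TriangleMesh, closest_points
from facedev.regional_analysis import RegionAtlas, summarize_regions

#: Expression-stable fitting regions: forehead, temples, nose, cheekbones.
DEFAULT_MASK_REGIONS = frozenset(
    {
        "frontal region",
        "temporal region",
        "nasal bridge L",
        "nasal bridge R",
        "apex of nose",
        "zygomatic region",
    }
)

#: Landmarks used for the coarse fit, in a fixed order.
LANDMARK_ORDER = (
    "glabella",
    "temple L",
    "temple R",
    "pronasale",
    "zygion L",
    "zygion R",
)


class DegenerateGeometryError(ValueError):
    """Point configuration too degenerate for a unique rigid fit."""


@dataclass(frozen=True)
class AlignmentMask:
    """Named atlas regions whose vertices drive the fine registration."""

    regions: frozenset = DEFAULT_MASK_REGIONS

    def resolve(self, atlas: RegionAtlas) -> np.ndarray:
        if not self.regions:
            raise ValueError("alignment mask is empty")
        missing = set(self.regions) - set(atlas.region_names)
        if missing:
            raise ValueError(f"mask regions absent from atlas: {sorted(missing)}")
        sel = np.isin(atlas.labels, list(self.regions))
        return np.flatnonzero(sel)


@dataclass
class RegistrationReport:
    transform: RigidTransform
    rms_history: list[float] = field(default_factory=list)
    iterations: int = 0
    trimmed_fraction: float = 0.1
    converged: bool = False


def kabsch(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping source onto target.

    Reflections are rejected via the usual determinant sign correction.
    """
    P = np.asarray(source_points, dtype=np.float64)
    Q = np.asarray(target_points, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    if len(P) < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq
    scale = max(np.abs(Pc).max(), 1e-30)
    if np.linalg.svd(Pc / scale, compute_uv=False)[1] < 1e-9:
        raise DegenerateGeometryError("source points are collinear or coincident")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


def landmark_align(
    scan_landmarks: Mapping[str, np.ndarray],
    shell_landmarks: Mapping[str, np.ndarray],
    names: Sequence[str] = LANDMARK_ORDER,
) -> RigidTransform:
    """Coarse alignment from named corresponding landmarks."""
    common = [n for n in names if n in scan_landmarks and n in shell_landmarks]
    if len(common) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 shared landmarks, have {len(common)}"
        )
    src = np.array([scan_landmarks[n] for n in common], dtype=np.float64)
    dst = np.array([shell_landmarks[n] for n in common], dtype=np.float64)
    return kabsch(src, dst)


def _params(T: RigidTransform) -> np.ndarray:
    """6-parameter chart (rotation vector, translation) of a transform."""
    from scipy.spatial.transform import Rotation

    return np.concatenate(
        [Rotation.from_matrix(T.rotation).as_rotvec(), T.translation]
    )


def _from_params(p: np.ndarray) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    return RigidTransform(Rotation.from_rotvec(p[:3]).as_matrix(), p[3:])


def _extrapolate(p_prev2, p_prev, p_cur, cap: float = 100.0):
    """Besl-style acceleration: extrapolate along the latest parameter
    increment when successive increments are aligned and geometrically
    shrinking (linear convergence).  Returns None when not applicable."""
    d1 = p_prev - p_prev2
    d2 = p_cur - p_prev
    n1 = np.linalg.norm(d1)
    n2 = np.linalg.norm(d2)
    if n1 < 1e-300 or n2 < 1e-300 or n2 >= n1:
        return None
    if float(d1 @ d2) / (n1 * n2) < 0.7:
        return None
    r = n2 / n1
    factor = min(r / (1.0 - r), cap)
    return p_cur + factor * d2


def icp(
    scan: TriangleMesh,
    shell: TriangleMesh,
    init: RigidTransform,
    mask: AlignmentMask,
    scan_atlas: RegionAtlas,
    trim: float = 0.1,
    tol: float = 1e-4,
    max_iter: int = 100,
    min_mask_vertices: int = 100,
) -> RegistrationReport:
    """Trimmed point-to-point ICP of scan mask vertices onto the shell.

    Deterministic given inputs: no randomness inside the loop.  Plain
    point-to-point ICP converges linearly (and slowly, via tangential
    sliding on smooth areas), so accepted increments are over-relaxed with
    an adaptive factor; overshoots revert to the best fit so the recorded
    kept-correspondence RMS stays non-increasing.
    """
    if not np.isfinite(scan.vertices).all() or not np.isfinite(shell.vertices).all():
        raise ValueError("non-finite coordinates")
    idx = mask.resolve(scan_atlas)
    if len(idx) < min_mask_vertices:
        raise ValueError(
            f"alignment mask resolves to {len(idx)} vertices "
            f"(minimum {min_mask_vertices})"
        )
    src = scan.vertices[idx]
    T = init
    best_T = T
    best_rms = np.inf
    history: list[float] = []
    param_trail: list[np.ndarray] = []  # plain-step parameter trajectory
    pending_plain: Optional[RigidTransform] = None  # fallback if a jump fails
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cur = T.apply(src)
        d, pts, _, on_boundary = closest_points(cur, shell)
        ok = ~on_boundary
        if not ok.any():
            raise ValueError("all correspondences rejected (boundary)")
        if trim > 0:
            cutoff = np.quantile(d[ok], 1.0 - trim)
            kept = ok & (d <= cutoff)
        else:
            kept = ok
        rms = float(np.sqrt(np.mean(d[kept] ** 2)))
        if rms > best_rms + 1e-12:
            if pending_plain is not None:
                # accelerated jump overshot: retreat to the plain step
                T = pending_plain
                pending_plain = None
                param_trail.clear()
                continue
            # plain step increased the objective (trim churn): stop
            T = best_T
            converged = True
            break
        history.append(rms)
        if best_rms - rms < tol:
            best_T, best_rms = T, rms
            converged = True
            break
        best_T, best_rms = T, rms
        step = kabsch(src[kept], pts[kept])
        pending_plain = None
        param_trail.append(_params(step))
        T = step
        if len(param_trail) >= 3:
            jump = _extrapolate(*param_trail[-3:])
            if jump is not None:
                pending_plain = step
                param_trail.clear()
                T = _from_params(jump)
    return RegistrationReport(
        transform=best_T,
        rms_history=history,
        iterations=it,
        trimmed_fraction=trim,
        converged=converged,
    )


def register(
    scan: TriangleMesh,
    shell: TriangleMesh,
    scan_landmarks: Mapping[str, np.ndarray],
    shell_landmarks: Mapping[str, np.ndarray],
    scan_atlas: RegionAtlas,
    mask: Optional[AlignmentMask] = None,
    **icp_opts,
) -> RegistrationReport:
    """Landmark-seeded coarse fit followed by trimmed ICP."""
    init = landmark_align(scan_landmarks, shell_landmarks)
    return icp(scan, shell, init, mask or AlignmentMask(), scan_atlas, **icp_opts)


@dataclass
class AgreementReport:
    agreement: bool
    max_disagreement_mm: float
    transform_spread_mm: float
    per_restart_p95: list[dict]
    transforms: list[RigidTransform]


def dual_operator_check(
    scan: TriangleMesh,
    shell: TriangleMesh,
    init: RigidTransform,
    mask: AlignmentMask,
    scan_atlas: RegionAtlas,
    n_restarts: int = 5,
    jitter: tuple[float, float] = (3.0, 2.0),
    seed: int = 0,
    agreement_tol_mm: float = 0.1,
    transform_tol_mm: float = 1.0,
    min_region_vertices: int = 20,
    **icp_opts,
) -> AgreementReport:
    """Stability check emulating independent operators.

    Re-runs ICP from jittered initial positions and compares both the
    final per-region 95th-percentile deviations and the final transforms
    themselves.  "Agreement" requires the maximum pairwise p95
    disagreement to stay under ``agreement_tol_mm`` AND the maximum
    pairwise surface displacement between final transforms to stay under
    ``transform_tol_mm`` — the latter catches rotationally symmetric
    geometry, where every fit yields identical deviations through
    genuinely different alignments.
    """
    rng = np.random.default_rng(seed)
    jd, jt = jitter
    per_restart: list[dict] = []
    transforms: list[RigidTransform] = []
    for _ in range(n_restarts):
        perturb = RigidTransform.from_euler_deg(
            tuple(rng.uniform(-jd, jd, size=3)), rng.uniform(-jt, jt, size=3)
        )
        report = icp(scan, shell, perturb.compose(init), mask, scan_atlas, **icp_opts)
        aligned = scan.transformed(report.transform)
        fieldv = absolute_deviation(aligned, shell)
        summaries = summarize_regions(fieldv, scan_atlas, min_vertices=min_region_vertices)
        per_restart.append(
            {s.region: s.p95_mm for s in summaries if s.assessable}
        )
        transforms.append(report.transform)
    common = set.intersection(*(set(d) for d in per_restart)) if per_restart else set()
    disagreement = 0.0
    for region in common:
        vals = [d[region] for d in per_restart]
        disagreement = max(disagreement, max(vals) - min(vals))
    probe = scan.vertices[mask.resolve(scan_atlas)]
    spread = 0.0
    for i in range(len(transforms)):
        for j in range(i + 1, len(transforms)):
            diff = transforms[i].apply(probe) - transforms[j].apply(probe)
            spread = max(spread, float(np.linalg.norm(diff, axis=1).mean()))
    return AgreementReport(
        agreement=disagreement < agreement_tol_mm and spread < transform_tol_mm,
        max_disagreement_mm=disagreement,
        transform_spread_mm=spread,
        per_restart_p95=per_restart,
        transforms=transforms,
    )
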