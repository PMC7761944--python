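"""Rigid superimposition of serial dental meshes.

The registration dialect reproduced here is a trimmed iterative closest
point scheme: each iteration samples the reference-region vertices of the
source model, finds the exact closest point on the target surface for each,
optionally discards pairs whose closest point lies on an open boundary of
the target ("exclude overhangs"), keeps the fraction of best-matching pairs
given by the *estimated overlap of meshes*, and solves a rigid update by a
point-to-plane (linearised) or point-to-point (Procrustes) least-squares
step.  Registrations with an estimated overlap below 50% are always
preceded by a full-overlap approximation stage, starting from the landmark
based coarse alignment that stands in for on-screen manual approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import RegionMask, RigidTransform, TriangleMesh
from .errors import (
    DegenerateInputError,
    InvalidInputError,
    NoCorrespondenceError,
)
from .geometry import MeshDistance

log = logging.getLogger(__name__)


@dataclass
class ICPSettings:
    """ICP dialect parameters.

    overlap_fraction
        Estimated overlap of meshes: the fraction of closest-point pairs,
        ranked by distance, retained each iteration (1.0, 0.4 and 0.2 are
        the fixed settings used by the techniques; 1.0 is the default).
    matching
        "point_to_plane" (default) or "point_to_point".
    sampling_fraction
        Fraction of the source reference vertices used (default 1.0).
    exclude_overhangs
        Reject pairs whose closest point lies on an open boundary of the
        target, so structure present in only one model cannot bias the fit.
    max_iterations / convergence_tol
        Iteration cap (default 50) and RMS-change stopping threshold in mm.
    outlier_rejection
        Optional robust gate: drop pairs farther than this multiple of the
        median correspondence distance before trimming.  Off by default (the
        predefined technique settings use pure overlap trimming); the staged
        approximation pass enables it so that grossly changed surface
        (a worn facet, a retainer) cannot drag a pass meant only to
        approximate the models.
    """

    overlap_fraction: float = 1.0
    matching: str = "point_to_plane"
    sampling_fraction: float = 1.0
    exclude_overhangs: bool = True
    max_iterations: int = 50
    convergence_tol: float = 1e-7
    outlier_rejection: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise InvalidInputError("overlap_fraction must be in (0, 1]")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise InvalidInputError("sampling_fraction must be in (0, 1]")
        if self.matching not in ("point_to_plane", "point_to_point"):
            raise InvalidInputError(f"unknown matching mode {self.matching!r}")
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be >= 1")

    def replace(self, **kw) -> "ICPSettings":
        d = self.__dict__.copy()
        d.update(kw)
        return ICPSettings(**d)


@dataclass
class RegistrationResult:
    """Cumulative rigid transform (source frame → target frame) plus diagnostics."""

    transform: RigidTransform
    rms_residual: float
    retained_count: int
    iterations_run: int
    stages: list[str] = field(default_factory=list)
    rms_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def coarse_align(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit of corresponding point pairs (Kabsch/Procrustes).

    Stands in for the operator's on-screen manual approximation; needs at
    least three non-collinear pairs.
    """
    p = np.asarray(source_points, dtype=np.float64).reshape(-1, 3)
    q = np.asarray(target_points, dtype=np.float64).reshape(-1, 3)
    if len(p) < 3 or len(p) != len(q):
        raise DegenerateInputError("need >= 3 corresponding point pairs")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    a = p - pc
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        raise DegenerateInputError("source landmarks are collinear")
    h = a.T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, qc - r @ pc)


def find_correspondences(
    source_sample: np.ndarray,
    target_mesh: TriangleMesh,
    exclude_overhangs: bool = True,
    engine: MeshDistance | None = None,
):
    """Exact closest point on the target surface for each sampled source point.

    Returns (kept source indices, closest points, distances, target normals):
    with ``exclude_overhangs`` pairs touching an open target boundary are
    dropped.
    """
    pts = np.asarray(source_sample, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        raise InvalidInputError("empty source sample")
    if engine is None:
        engine = MeshDistance(target_mesh)
    hits = engine.query(pts)
    keep = ~hits.on_boundary if exclude_overhangs else np.ones(len(pts), dtype=bool)
    idx = np.nonzero(keep)[0]
    return idx, hits.points[keep], hits.distances[keep], hits.normals[keep]


def trim_correspondences(distances: np.ndarray, overlap_fraction: float) -> np.ndarray:
    """Indices of the k = max(1, floor(f·n)) smallest distances.

    Stable: ties are broken by original (source) order, and the returned
    indices are sorted ascending by source order.
    """
    d = np.asarray(distances, dtype=np.float64)
    if len(d) == 0:
        raise InvalidInputError("no correspondences to trim")
    k = max(1, int(np.floor(overlap_fraction * len(d))))
    order = np.argsort(d, kind="stable")
    return np.sort(order[:k])


def _solve_point_to_point(p: np.ndarray, q: np.ndarray) -> RigidTransform:
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, qc - r @ pc)


def _solve_point_to_plane(p: np.ndarray, q: np.ndarray, n: np.ndarray) -> RigidTransform:
    """Small-angle linearised point-to-plane step; exact rotation rebuilt from
    the solved rotation vector (re-orthonormalisation)."""
    a = np.hstack([np.cross(p, n), n])           # (k, 6)
    b = np.einsum("ij,ij->i", q - p, n)
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    r = Rotation.from_rotvec(x[:3]).as_matrix()
    return RigidTransform(r, x[3:])


def icp_register(
    source_mesh: TriangleMesh,
    source_region: RegionMask,
    target_mesh: TriangleMesh,
    settings: ICPSettings,
    initial: RigidTransform | None = None,
    seed: int = 0,
    engine: MeshDistance | None = None,
) -> RegistrationResult:
    """Trimmed ICP of the source reference region onto the target surface.

    Correspondences run single-direction, source region → target surface.
    Returns the cumulative transform from the initial position.
    """
    source_region.validate(source_mesh)
    if initial is None:
        initial = RigidTransform.identity()
    if engine is None:
        engine = MeshDistance(target_mesh)

    pts0 = source_mesh.vertices[source_region.indices]
    if settings.sampling_fraction < 1.0:
        rng = np.random.default_rng(seed)
        k = max(3, int(np.floor(settings.sampling_fraction * len(pts0))))
        pts0 = pts0[np.sort(rng.choice(len(pts0), size=k, replace=False))]

    transform = initial
    prev_rms = np.inf
    rms = np.inf
    retained = 0
    history: list[float] = []
    it = 0
    for it in range(1, settings.max_iterations + 1):
        p = transform.apply(pts0)
        hits = engine.query(p)
        keep = (
            ~hits.on_boundary
            if settings.exclude_overhangs
            else np.ones(len(p), dtype=bool)
        )
        if not keep.any():
            raise NoCorrespondenceError("all correspondences rejected as overhangs")
        if settings.outlier_rejection is not None:
            med = float(np.median(hits.distances[keep]))
            keep &= hits.distances <= settings.outlier_rejection * med + 1e-12
            if not keep.any():
                raise NoCorrespondenceError("all correspondences rejected as outliers")
        d = hits.distances[keep]
        sel = trim_correspondences(d, settings.overlap_fraction)
        pk = p[keep][sel]
        qk = hits.points[keep][sel]
        nk = hits.normals[keep][sel]
        retained = len(sel)
        rms = float(np.sqrt(np.mean(d[sel] ** 2)))
        history.append(rms)
        if abs(prev_rms - rms) < settings.convergence_tol:
            break
        prev_rms = rms
        if settings.matching == "point_to_plane":
            try:
                # lstsq handles rank-deficient normal sets (flat regions) by
                # the minimum-norm update; a hard failure falls back to the
                # Procrustes point-to-point step
                step = _solve_point_to_plane(pk, qk, nk)
            except (np.linalg.LinAlgError, DegenerateInputError):
                step = _solve_point_to_point(pk, qk)
        else:
            step = _solve_point_to_point(pk, qk)
        transform = step.compose(transform)

    return RegistrationResult(transform, rms, retained, it, rms_history=history)


def staged_register(
    source_mesh: TriangleMesh,
    source_region: RegionMask,
    target_mesh: TriangleMesh,
    settings: ICPSettings,
    landmark_pairs: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    engine: MeshDistance | None = None,
) -> RegistrationResult:
    """Coarse landmark alignment, then staged ICP.

    Whenever the requested estimated overlap is below 50%, a full-overlap
    approximation pass runs between the coarse alignment and the final
    setting; the whole pipeline always starts from the models' original
    initial position (the composed transform is relative to it).
    """
    src_lm, tgt_lm = landmark_pairs
    if engine is None:
        engine = MeshDistance(target_mesh)
    stages = ["coarse"]
    transform = coarse_align(src_lm, tgt_lm)
    if settings.overlap_fraction < 0.5:
        stages.append("approximation_100")
        # a *partial* approximation: full estimated overlap, robustified so
        # that surface present in only one model cannot drag a pass whose
        # only job is to bring the models close for the final setting
        pre = icp_register(
            source_mesh, source_region, target_mesh,
            settings.replace(overlap_fraction=1.0, outlier_rejection=6.0),
            initial=transform, seed=seed, engine=engine,
        )
        transform = pre.transform
    stages.append(f"final_{settings.overlap_fraction:g}")
    final = icp_register(
        source_mesh, source_region, target_mesh, settings,
        initial=transform, seed=seed, engine=engine,
    )
    log.debug("staged_register stages=%s rms=%.3g", stages, final.rms_residual)
    return RegistrationResult(
        final.transform,
        final.rms_residual,
        final.retained_count,
        final.iterations_run,
        stages=stages,
        rms_history=final.rms_history,
    )


def optimize_overlap_fraction(
    source_mesh: TriangleMesh,
    source_region: RegionMask,
    target_mesh: TriangleMesh,
    intact_region: RegionMask,
    landmark_pairs: tuple[np.ndarray, np.ndarray],
    grid: np.ndarray | None = None,
    settings: ICPSettings | None = None,
    seed: int = 0,
) -> tuple[float, dict[float, float]]:
    """Grid search for the estimated-overlap value giving the best fit of the
    intact structures ("user defined" overlap).

    Emulates the operator's iterative search: for every fraction on the grid
    a staged registration runs, and the RMS distance of the (known intact)
    region to the target surface under the found transform scores it.  Ties
    within numerical noise resolve toward the largest fraction.  Only usable
    in benchmark/synthetic settings where an intact region is known.
    """
    if grid is None:
        grid = np.round(np.arange(0.05, 1.0001, 0.05), 2)
    grid = np.asarray(grid, dtype=np.float64)
    if len(grid) == 0:
        raise InvalidInputError("empty overlap grid")
    if settings is None:
        settings = ICPSettings()
    intact_region.validate(source_mesh)
    engine = MeshDistance(target_mesh)
    intact_pts = source_mesh.vertices[intact_region.indices]
    scores: dict[float, float] = {}
    for f in grid:
        res = staged_register(
            source_mesh, source_region, target_mesh,
            settings.replace(overlap_fraction=float(f)),
            landmark_pairs, seed=seed, engine=engine,
        )
        hits = engine.query(res.transform.apply(intact_pts))
        scores[float(f)] = float(np.sqrt(np.mean(hits.distances ** 2)))
    best_rms = min(scores.values())
    tol = best_rms * 1e-6 + 1e-12
    best = max(f for f, s in scores.items() if s <= best_rms + tol)
    return best, scores
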