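"""Wear volumetrics: distance maps, simultaneous plane slicing, identical
hole filling and the wear-volume difference.

After superimposition the T0 and T1 crowns are sliced with the *same*
planes, each hole boundary is split into planar loops where planes meet,
the loops are capped identically (planar ear-clipping), and wear is the
volume difference of the two watertight occlusal parts:

    wear = V(T0 part) − V(T1 part)   [mm³, positive for material loss]

Identical planes and identical capping make everything below the cut cancel
exactly, so the difference isolates the occlusal change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    RegionMask,
    RigidTransform,
    TriangleMesh,
    boundary_loops,
    is_watertight,
    mesh_volume,
    submesh,
)
from .errors import (
    CannotIsolateError,
    EmptyPartError,
    GeometryError,
    InvalidInputError,
    TopologyError,
)
from .geometry import MeshDistance, clip_half_space, triangulate_planar_polygon, _plane_basis
from .registration import ICPSettings
from .techniques import TechniqueSpec, run_technique

log = logging.getLogger(__name__)

#: planarity tolerance for hole loops (mm)
LOOP_PLANAR_TOL = 1e-6
#: default colour-map threshold deciding "changed" surface (mm)
DEFAULT_DISTANCE_THRESHOLD = 0.05
#: gingival plane clearance below the lowest changed vertex (mm)
PLANE_OFFSET = 0.3


@dataclass(frozen=True)
class SlicePlane:
    """A slicing plane; ``normal`` is unit and points into the kept half-space."""

    point: np.ndarray
    normal: np.ndarray
    role: str = "gingival"

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=np.float64).reshape(3))
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise InvalidInputError("slice plane normal must be non-zero")
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.point) @ self.normal


@dataclass
class WearMeasurement:
    """Result of one wear measurement."""

    technique_id: str
    t0_part_volume: float
    t1_part_volume: float
    wear_volume: float
    planes: list[SlicePlane] = field(default_factory=list)
    watertight: tuple[bool, bool] = (True, True)
    rms_residual: float = float("nan")
    transform: RigidTransform | None = None


# ---------------------------------------------------------------------------
# distance maps
# ---------------------------------------------------------------------------

def distance_map(source: TriangleMesh, target: TriangleMesh) -> np.ndarray:
    """Signed distance (mm) of each source vertex to the target surface.

    Positive where the source lies outside the target surface (along the
    target's outward normal); the convention is arbitrary but fixed.
    """
    engine = MeshDistance(target.validate())
    hits = engine.query(source.validate().vertices)
    return hits.signed


# ---------------------------------------------------------------------------
# plane placement
# ---------------------------------------------------------------------------

def propose_slice_planes(
    t0_crown: TriangleMesh,
    t1_crown_aligned: TriangleMesh,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    gingival_limit: float | None = None,
    occlusal_axis: np.ndarray = (0.0, 0.0, 1.0),
    extra_planes: list[SlicePlane] | None = None,
    plane_offset: float = PLANE_OFFSET,
) -> tuple[list[SlicePlane], np.ndarray]:
    """Place the gingival slicing plane under the occlusal changed region.

    The distance map between the superimposed crowns marks changed surface
    (|d| > threshold).  The changed cluster connected to the occlusal-most
    change must be fully on the occlusal side of the gingival plane, which
    is placed ``plane_offset`` below its lowest vertex; the plane must stay
    above ``gingival_limit`` (the gingival end of the crown region).  Caller
    supplied ``extra_planes`` (mesial/distal) are passed through.  All
    planes are then verified: the retained cut lines of both models must
    show |distance| below the threshold, otherwise the changed region
    cannot be isolated.

    Returns (planes, signed distance map on the T0 crown).
    """
    axis = np.asarray(occlusal_axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    d = distance_map(t0_crown, t1_crown_aligned)
    height = t0_crown.vertices @ axis
    if gingival_limit is None:
        gingival_limit = float(height.min())
    changed = np.abs(d) > distance_threshold

    if not changed.any():
        level = gingival_limit + 0.5 * (float(height.max()) - gingival_limit)
        candidate_levels = [level]
    else:
        cluster = _occlusal_cluster(t0_crown, changed, height)
        top = float(height[cluster].min())
        # like the operator, try successively more gingival positions until
        # the cut line verifiably runs through unchanged surface
        candidate_levels = [
            lv for lv in (top - plane_offset - k * 0.3 for k in range(4))
            if lv > gingival_limit + 0.05
        ]
        if not candidate_levels:
            raise CannotIsolateError(
                "changed region reaches the gingival end of the crown; "
                "no admissible gingival plane"
            )
    last_err: CannotIsolateError | None = None
    for level in candidate_levels:
        planes = [SlicePlane(axis * level, axis, "gingival")]
        if extra_planes:
            planes = planes + list(extra_planes)
        try:
            _verify_cut_lines(t0_crown, t1_crown_aligned, planes, distance_threshold)
            return planes, d
        except CannotIsolateError as exc:
            last_err = exc
    raise last_err


def _occlusal_cluster(mesh: TriangleMesh, changed: np.ndarray, height: np.ndarray) -> np.ndarray:
    """Vertices of the changed component(s) reaching the occlusal-most change."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    idx = np.nonzero(changed)[0]
    sub = -np.ones(mesh.n_vertices, dtype=np.int64)
    sub[idx] = np.arange(len(idx))
    f = mesh.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = e[changed[e].all(axis=1)]
    n = len(idx)
    adj = coo_matrix((np.ones(len(e)), (sub[e[:, 0]], sub[e[:, 1]])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    top = labels[np.argmax(height[idx])]
    # all components whose top comes close to the overall top join the cluster
    zmax = height[idx].max()
    keep = np.zeros(n, dtype=bool)
    for lab in np.unique(labels):
        if height[idx[labels == lab]].max() >= zmax - 0.25:
            keep |= labels == lab
    keep[labels == top] = True
    return idx[keep]


def _verify_cut_lines(
    t0: TriangleMesh,
    t1: TriangleMesh,
    planes: list[SlicePlane],
    threshold: float,
) -> None:
    """Check that the retained cut boundaries lie in unchanged surface."""
    for src, tgt in ((t0, t1), (t1, t0)):
        try:
            part = slice_with_planes(src, planes)
        except EmptyPartError as exc:
            raise CannotIsolateError(f"slicing plane removes the whole model: {exc}") from exc
        loops = boundary_loops(part)
        if not loops:
            continue
        ring = np.concatenate([part.vertices[lp] for lp in loops])
        engine = MeshDistance(tgt)
        dist = engine.query(ring).distances
        worst = float(dist.max())
        if worst >= threshold:
            raise CannotIsolateError(
                f"models differ by {worst:.3f} mm at a slicing edge "
                f"(threshold {threshold:g} mm)"
            )


# ---------------------------------------------------------------------------
# slicing and hole filling
# ---------------------------------------------------------------------------

def slice_with_planes(mesh: TriangleMesh, planes: list[SlicePlane]) -> TriangleMesh:
    """Keep the intersection of the kept half-spaces (the occlusal part).

    Crossing triangles are split exactly at each plane; after all cuts the
    boundary vertices are re-projected so that each lies on every plane it
    belongs to within 1e-9 mm (corner vertices land on plane intersections).
    """
    if not planes:
        raise InvalidInputError("no slicing planes given")
    part = mesh
    for pl in planes:
        part = clip_half_space(part, pl.point, pl.normal)
        if part.n_faces == 0:
            raise EmptyPartError(f"plane {pl.role} removes the whole mesh")
    # settle vertices onto every plane they are close to (corner vertices
    # converge onto the planes' intersection line)
    v = part.vertices
    for _ in range(3):
        for pl in planes:
            s = (v - pl.point) @ pl.normal
            close = np.abs(s) < 1e-6
            v[close] -= np.outer(s[close], pl.normal)
    return part


def split_hole(
    part: TriangleMesh, loop: np.ndarray, planes: list[SlicePlane]
) -> list[np.ndarray]:
    """Split a slicing-hole boundary cycle into planar loops.

    A loop whose vertices already lie on a single plane is returned as is.
    Otherwise a chord is inserted along the intersection line of each pair
    of adjacent slicing planes, between the two loop vertices sitting on
    that crease, and the pieces are split recursively — the in-silico
    version of connecting contralateral points across sharp edges so every
    hole edge lies on one plane.
    """
    loop = np.asarray(loop, dtype=np.int64)
    on = _on_plane_matrix(part, loop, planes)

    def rec(sub_positions: np.ndarray, depth: int) -> list[np.ndarray]:
        sub_on = on[sub_positions]
        if sub_on.all(axis=0).any():
            return [loop[sub_positions]]
        if depth > len(planes) + 2:
            raise TopologyError("hole loop cannot be split into planar pieces")
        npl = len(planes)
        for a in range(npl):
            for b in range(a + 1, npl):
                corners = np.nonzero(sub_on[:, a] & sub_on[:, b])[0]
                if len(corners) < 2:
                    continue
                # chord between the two crease vertices that best splits the
                # loop: take the pair that leaves both pieces non-trivial
                for i in range(len(corners)):
                    for j in range(i + 1, len(corners)):
                        ci, cj = corners[i], corners[j]
                        piece1 = sub_positions[ci : cj + 1]
                        piece2 = np.concatenate([sub_positions[cj:], sub_positions[: ci + 1]])
                        if len(piece1) < 3 or len(piece2) < 3:
                            continue
                        try:
                            return rec(piece1, depth + 1) + rec(piece2, depth + 1)
                        except TopologyError:
                            continue
        raise TopologyError("hole loop cannot be split with the available planes")

    return rec(np.arange(len(loop)), 0)


def _on_plane_matrix(
    part: TriangleMesh, loop: np.ndarray, planes: list[SlicePlane]
) -> np.ndarray:
    pts = part.vertices[loop]
    on = np.zeros((len(loop), len(planes)), dtype=bool)
    for k, pl in enumerate(planes):
        on[:, k] = np.abs(pl.signed_distance(pts)) < LOOP_PLANAR_TOL
    return on


def fill_holes(part: TriangleMesh, planar_loops: list[np.ndarray]) -> TriangleMesh:
    """Cap each planar loop by ear-clipping it in its plane.

    Loops must be oriented as produced by :func:`boundary_loops`; caps are
    built on the reversed traversal so their winding continues the part's
    outward orientation.  The capped mesh must come out watertight.
    """
    faces = [part.faces]
    for loop in planar_loops:
        loop = np.asarray(loop, dtype=np.int64)
        if len(np.unique(loop)) != len(loop):
            raise GeometryError("hole loop revisits a vertex (not a simple polygon)")
        pts = part.vertices[loop]
        centre, normal, res = _fit_plane(pts)
        if res > LOOP_PLANAR_TOL * 10:
            raise GeometryError(f"hole loop is not planar (residual {res:.2e} mm)")
        u, v = _plane_basis(normal)
        rev = loop[::-1]
        p2 = np.column_stack([(part.vertices[rev] - centre) @ u, (part.vertices[rev] - centre) @ v])
        tris = triangulate_planar_polygon(p2)
        faces.append(rev[tris])
    capped = TriangleMesh(part.vertices.copy(), np.vstack(faces))
    if not is_watertight(capped):
        raise TopologyError("capped part is not watertight")
    return capped


def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    from .geometry import fit_plane

    return fit_plane(points)


def close_part(part: TriangleMesh, planes: list[SlicePlane]) -> TriangleMesh:
    """Split every hole of a sliced part into planar loops and cap them."""
    loops = boundary_loops(part)
    planar: list[np.ndarray] = []
    for lp in loops:
        planar.extend(split_hole(part, lp, planes))
    return fill_holes(part, planar)


def sliced_volume_difference(
    t0_tooth: TriangleMesh,
    t1_tooth_aligned: TriangleMesh,
    planes: list[SlicePlane],
) -> tuple[float, float, float]:
    """Slice both models with the same planes, cap identically, and return
    (V0, V1, V0 − V1)."""
    part0 = close_part(slice_with_planes(t0_tooth, planes), planes)
    part1 = close_part(slice_with_planes(t1_tooth_aligned, planes), planes)
    v0 = mesh_volume(part0)
    v1 = mesh_volume(part1)
    return v0, v1, v0 - v1


# ---------------------------------------------------------------------------
# end-to-end measurement
# ---------------------------------------------------------------------------

def measure_wear(
    t0_model: TriangleMesh,
    t1_model: TriangleMesh,
    labels: dict[str, RegionMask],
    technique: TechniqueSpec | str,
    landmarks: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    settings: ICPSettings | None = None,
    extra_planes: list[SlicePlane] | None = None,
    return_artifacts: bool = False,
):
    """Full pipeline: superimpose, slice simultaneously, fill identically,
    and measure the occlusal wear volume.

    ``labels`` are defined on T0 and must include ``tooth`` (all vertices of
    the measured tooth) and ``tooth_t1`` (the same tooth on T1), plus the
    reference-area labels the technique needs.  Wear is reported as
    V(T0 part) − V(T1 part), positive for material loss.
    """
    reg = run_technique(t0_model, t1_model, labels, technique, landmarks,
                        seed=seed, settings=settings)
    tid = technique if isinstance(technique, str) else technique.id

    if "tooth" not in labels or "tooth_t1" not in labels:
        raise InvalidInputError("labels must include 'tooth' (T0) and 'tooth_t1' (T1)")
    t0_tooth, _ = submesh(t0_model, labels["tooth"].validate(t0_model).indices)
    t1_tooth, _ = submesh(t1_model, labels["tooth_t1"].validate(t1_model).indices)
    t1_aligned = t1_tooth.transformed(reg.transform)

    gingival_limit = None
    if "crown" in labels:
        gingival_limit = float(t0_model.vertices[labels["crown"].indices][:, 2].min())
    planes, dmap = propose_slice_planes(
        t0_tooth, t1_aligned, distance_threshold,
        gingival_limit=gingival_limit, extra_planes=extra_planes,
    )
    v0, v1, wear = sliced_volume_difference(t0_tooth, t1_aligned, planes)
    meas = WearMeasurement(
        technique_id=tid,
        t0_part_volume=v0,
        t1_part_volume=v1,
        wear_volume=wear,
        planes=planes,
        watertight=(True, True),
        rms_residual=reg.rms_residual,
        transform=reg.transform,
    )
    log.info("measure_wear %s: V0=%.4f V1=%.4f wear=%.4f mm^3", tid, v0, v1, wear)
    if return_artifacts:
        t0_map = t0_tooth.copy()
        t0_map.vertex_scalar = dmap
        return meas, {"distance_map": t0_map, "registration": reg, "planes": planes}
    return meas
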