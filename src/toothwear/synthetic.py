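"""In-silico replica of the bench experiment: parametric anterior teeth in a
short arch segment, occlusal grinding with closed-form ground truth, a
lingual retainer, scanner noise and the full benchmark factory.

The generator emulates the study conditions rather than anatomical scans:

* **teeth** are superellipse-profile crowns (thin incisal edge for
  incisors, single tapering cusp for canines) on tapered roots, watertight
  by construction, placed in a 3-tooth arch segment (test tooth flanked by
  intact neighbours) over an alveolar band;
* **grinding** truncates the occlusal end with a horizontal (symmetric) or
  tilted (asymmetric) plane at ≈0.5/1/2 mm vertical loss; the removed solid
  is capped and its volume measured, giving exact ground truth;
* **the retainer** (0.3 mm twisted wire plus composite blobs, bonded to the
  mid-lingual surfaces) is modelled as the outward envelope the scanner
  would see: lingual crown vertices are displaced outwards by a wire-ridge
  plus blob displacement field, leaving every buccal/occlusal vertex
  bit-identical;
* **scanner noise** displaces vertices along their normals by clamped
  zero-mean Gaussian offsets (SD 2 μm, never exceeding 5 μm), matching the
  repeated-scan surface deviation bound of a laboratory scanner;
* T1 is generated in a different pose (random rigid displacement, rotation
  ≤ 15°, translation ≤ 10 mm) and the coarse-alignment landmarks are
  jittered, so registration is always genuinely exercised.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import RegionMask, RigidTransform, TriangleMesh, concatenate, mesh_volume, weld_vertices
from .errors import GenerationError, InvalidSpecError, PlacementError
from .geometry import clip_half_space
from .wear import SlicePlane, close_part

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToothSpec:
    """One parametric tooth: type, crown size (mm) and mesh resolution."""

    tooth_type: str = "incisor"           # "incisor" | "canine"
    crown_height: float = 10.0
    mesiodistal: float = 8.0
    buccolingual: float = 7.0
    position: int = 0
    resolution: int = 1200                # target triangle count

    def __post_init__(self) -> None:
        if self.tooth_type not in ("incisor", "canine"):
            raise InvalidSpecError(f"unknown tooth type {self.tooth_type!r}")
        if min(self.crown_height, self.mesiodistal, self.buccolingual) <= 0:
            raise InvalidSpecError("tooth dimensions must be positive")
        if self.resolution < 500:
            raise InvalidSpecError("resolution must be >= 500 triangles")


@dataclass(frozen=True)
class WearSpec:
    """Occlusal grinding: vertical loss in mm, symmetric or tilted."""

    vertical_loss: float = 1.0
    pattern: str = "symmetric"            # "symmetric" | "asymmetric"
    tilt_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.vertical_loss < 0:
            raise InvalidSpecError("vertical_loss must be >= 0")
        if self.pattern not in ("symmetric", "asymmetric"):
            raise InvalidSpecError(f"unknown wear pattern {self.pattern!r}")
        if not (0 <= self.tilt_deg <= 30):
            raise InvalidSpecError("tilt must be within 0..30 degrees")


@dataclass(frozen=True)
class RetainerSpec:
    """Lingual retainer wire + composite blobs (scanner-visible envelope)."""

    wire_diameter: float = 0.3
    wire_height_frac: float = 0.42        # wire height as fraction of crown height
    blob_radius: float = 1.6              # lateral extent of a composite blob, mm
    blob_height: float = 0.7              # blob proudness over the surface, mm

    def __post_init__(self) -> None:
        if self.wire_diameter <= 0:
            raise InvalidSpecError("wire_diameter must be > 0")


@dataclass(frozen=True)
class ScanNoiseSpec:
    """Scanner noise along vertex normals: Gaussian SD, hard clamp, seed."""

    sd: float = 0.002
    max_dev: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0 or self.max_dev < self.sd:
            raise InvalidSpecError("need 0 <= sd <= max_dev")


@dataclass
class ArchComponent:
    """One closed component of the scene with its local masks/landmarks."""

    name: str
    mesh: TriangleMesh
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class WearCase:
    """One synthetic test case with ground truth."""

    case_id: str
    t0_model: TriangleMesh
    t1_model: TriangleMesh
    labels: dict[str, RegionMask]
    landmarks: tuple[np.ndarray, np.ndarray]
    true_removed_volume: float
    tooth_type: str = "incisor"
    loss_level: float = 1.0
    pattern: str = "symmetric"
    crowding: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# parametric tooth
# ---------------------------------------------------------------------------

def _ramp(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smoothstep from 0 at lo to 1 at hi."""
    t = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return t * t * (3 - 2 * t)


def make_tooth(spec: ToothSpec, root_depth: float = 5.0, seed: int = 0) -> ArchComponent:
    """Closed tooth mesh in its local frame.

    Local frame: x mesiodistal, y buccolingual (buccal = −y), z occlusal;
    the gingival margin sits at z = 0, the root reaches −``root_depth``.

    The crown carries seeded low-frequency radial relief (marginal-ridge /
    fossa scale bumps of a few tenths of a millimetre): real crowns are far
    from surfaces of revolution, and that anatomy is what lets a
    crown-referenced registration lock all six degrees of freedom.
    """
    res = spec.resolution
    n_theta = max(16, int(round(np.sqrt(res / 3.2))))
    n_u = max(14, int(round(res / (2 * n_theta))) + 1)
    h = spec.crown_height
    a0, b0 = spec.mesiodistal / 2.0, spec.buccolingual / 2.0
    p = 2.6 if spec.tooth_type == "incisor" else 2.0

    z = np.concatenate(
        [
            np.linspace(-root_depth, -1e-3, max(4, n_u // 4)),
            np.linspace(0.0, 0.985 * h, n_u),
        ]
    )
    zc = np.clip(z / h, 0.0, 1.0)
    root_t = np.clip((z + root_depth) / root_depth, 0.0, 1.0)
    base = np.where(z < 0, 0.55 + 0.43 * root_t, 0.98 + 0.04 * np.sin(np.pi * np.clip(zc, 0, 1) * 0.9))
    if spec.tooth_type == "incisor":
        # blade-like: broad mesiodistally, thinning to a narrow incisal edge
        a_sc = base * (1.0 - 0.25 * _ramp(zc, 0.60, 1.0))
        b_sc = base * (1.0 - 0.95 * _ramp(zc, 0.40, 1.0))
    else:
        # single cusp: both widths taper strongly toward the tip
        a_sc = base * (1.0 - 0.90 * _ramp(zc, 0.35, 1.0))
        b_sc = base * (1.0 - 0.90 * _ramp(zc, 0.35, 1.0))
    a = np.maximum(a0 * a_sc, 0.08)
    b = np.maximum(b0 * b_sc, 0.08)

    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    cx = np.sign(ct) * np.abs(ct) ** (2.0 / p)
    cy = np.sign(st) * np.abs(st) ** (2.0 / p)

    # crown relief: deterministic anatomy (cingulum, marginal/labial ridges)
    # plus seeded low-frequency lobes.  Real crowns are far from surfaces of
    # revolution; this relief is what lets a crown-referenced registration
    # constrain all six degrees of freedom.
    rng = np.random.default_rng(seed)
    n_lobes = 5
    ms = rng.integers(2, 8, size=n_lobes)
    amps = rng.uniform(0.10, 0.30, size=n_lobes)
    phis = rng.uniform(0, 2 * np.pi, size=n_lobes)
    zfreq = rng.integers(1, 4, size=n_lobes)
    zphi = rng.uniform(0, 2 * np.pi, size=n_lobes)

    lingual = np.clip(st, 0.0, None)          # +y side
    buccal = np.clip(-st, 0.0, None)

    def anatomy(zci: float) -> np.ndarray:
        out = np.zeros(n_theta)
        if spec.tooth_type == "incisor":
            # cingulum bulge on the lingual third, a concave fossa above it
            # flanked by marginal ridges, and gentle buccal lobes
            out += 0.85 * np.exp(-(((zci - 0.20) / 0.13) ** 2)) * lingual**2
            out -= 0.55 * np.exp(-(((zci - 0.55) / 0.20) ** 2)) * lingual**4
            out += 0.45 * np.exp(-(((zci - 0.55) / 0.25) ** 2)) * lingual * np.sin(2 * theta) ** 2
            out += 0.30 * np.exp(-(((zci - 0.45) / 0.30) ** 2)) * buccal * np.cos(3 * theta)
        else:
            # labial and lingual ridges running toward the cusp
            out += 0.55 * np.exp(-(((zci - 0.45) / 0.25) ** 2)) * buccal**3
            out += 0.65 * np.exp(-(((zci - 0.25) / 0.15) ** 2)) * lingual**2
        return out

    nr = len(z)
    verts = np.empty((nr * n_theta + 2, 3))
    crown_env = _ramp(zc, 0.02, 0.25) * (1.0 - 0.6 * _ramp(zc, 0.8, 1.0))
    for i in range(nr):
        relief = anatomy(float(zc[i])).copy()
        for k in range(n_lobes):
            relief += amps[k] * np.cos(ms[k] * theta + phis[k]) * np.cos(
                zfreq[k] * np.pi * zc[i] + zphi[k]
            )
        scale = 1.0 + crown_env[i] * relief / max(a0, b0)
        verts[i * n_theta : (i + 1) * n_theta, 0] = a[i] * cx * scale
        verts[i * n_theta : (i + 1) * n_theta, 1] = b[i] * cy * scale
        verts[i * n_theta : (i + 1) * n_theta, 2] = z[i]
    bottom = nr * n_theta
    top = bottom + 1
    verts[bottom] = (0.0, 0.0, -root_depth - 0.4)
    verts[top] = (0.0, 0.0, h)

    faces: list[tuple[int, int, int]] = []
    for i in range(nr - 1):
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            v00, v01 = i * n_theta + j, i * n_theta + j2
            v10, v11 = (i + 1) * n_theta + j, (i + 1) * n_theta + j2
            faces.append((v00, v01, v11))
            faces.append((v00, v11, v10))
    for j in range(n_theta):
        j2 = (j + 1) % n_theta
        faces.append((j2, j, bottom))                                  # root cap
        faces.append(((nr - 1) * n_theta + j, (nr - 1) * n_theta + j2, top))  # incisal cap

    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64)).validate()

    crown = np.nonzero(verts[:, 2] > 1e-6)[0]
    buccal = crown[verts[crown, 1] < 0]
    lingual = crown[verts[crown, 1] >= 0]
    margin_ring = np.arange(len(np.nonzero(z < 0)[0]) * n_theta,
                            (len(np.nonzero(z < 0)[0]) + 1) * n_theta)
    gmid = margin_ring[np.argmin(verts[margin_ring, 1])]
    landmarks = {
        "tip": verts[top].copy(),
        "gingival_mid_buccal": verts[gmid].copy(),
        "mesial": verts[crown[np.argmax(verts[crown, 0])]].copy(),
        "distal": verts[crown[np.argmin(verts[crown, 0])]].copy(),
    }
    return ArchComponent(
        name=f"tooth_{spec.position}",
        mesh=mesh,
        masks={"crown": crown, "buccal": buccal, "lingual": lingual},
        landmarks=landmarks,
    )


def _face_grid(origin, du, dv, nu, nv):
    """Rectangular vertex grid + triangles wound so the normal follows du×dv."""
    origin, du, dv = (np.asarray(x, dtype=np.float64) for x in (origin, du, dv))
    ii, jj = np.meshgrid(np.arange(nu + 1), np.arange(nv + 1), indexing="ij")
    verts = origin + ii[..., None] * du + jj[..., None] * dv
    verts = verts.reshape(-1, 3)
    faces = []
    for i in range(nu):
        for j in range(nv):
            v00 = i * (nv + 1) + j
            v01 = v00 + 1
            v10 = (i + 1) * (nv + 1) + j
            v11 = v10 + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return verts, np.asarray(faces, dtype=np.int64)


def grid_box(lo, hi, cell: float = 1.2) -> TriangleMesh:
    """Axis-aligned watertight box subdivided into ~``cell``-sized quads."""
    lo = np.asarray(lo, dtype=np.float64)
    hi = np.asarray(hi, dtype=np.float64)
    size = hi - lo
    n = np.maximum(1, np.round(size / cell).astype(int))
    ex, ey, ez = np.eye(3) * size
    dx, dy, dz = ex / n[0], ey / n[1], ez / n[2]
    panels = [
        (lo, dy, dx, n[1], n[0]),                    # bottom  (-z): dy×dx = -z
        (lo + ez, dx, dy, n[0], n[1]),               # top     (+z)
        (lo, dx, dz, n[0], n[2]),                    # front   (-y): dx×dz = -y
        (lo + ey, dz, dx, n[2], n[0]),               # back    (+y)
        (lo, dz, dy, n[2], n[1]),                    # left    (-x)
        (lo + ex, dy, dz, n[1], n[2]),               # right   (+x)
    ]
    vs, fs, off = [], [], 0
    for origin, du, dv, nu, nv in panels:
        v, f = _face_grid(origin, du, dv, nu, nv)
        vs.append(v)
        fs.append(f + off)
        off += len(v)
    verts, faces = weld_vertices(np.vstack(vs), np.vstack(fs))
    return TriangleMesh(verts, faces).validate()


# ---------------------------------------------------------------------------
# arch assembly
# ---------------------------------------------------------------------------

def _place(component: ArchComponent, rot_z_deg: float, offset: np.ndarray) -> ArchComponent:
    r = Rotation.from_euler("z", rot_z_deg, degrees=True).as_matrix()
    t = RigidTransform(r, np.asarray(offset, dtype=np.float64))
    out = ArchComponent(
        component.name,
        component.mesh.transformed(t),
        {k: v.copy() for k, v in component.masks.items()},
        {k: t.apply(v) for k, v in component.landmarks.items()},
    )
    return out


def build_arch_components(
    specs: list[ToothSpec],
    crowding: bool = False,
    seed: int = 0,
    test_index: int | None = None,
) -> list[ArchComponent]:
    """Place the teeth side by side (x axis) and add the alveolar band."""
    if len(specs) < 3:
        raise GenerationError("an arch segment needs at least 3 teeth")
    rng = np.random.default_rng(seed)
    if test_index is None:
        test_index = len(specs) // 2
    gap = 1.4
    widths = [s.mesiodistal for s in specs]
    total = sum(widths) + gap * (len(specs) - 1)
    x = -total / 2.0
    comps: list[ArchComponent] = []
    jitter_scale = 1.0
    for attempt in range(6):
        comps = []
        x = -total / 2.0
        ok = True
        for i, s in enumerate(specs):
            tooth = make_tooth(replace(s, position=i), seed=int(rng.integers(2**31 - 1)))
            rot = 0.0
            dy = 0.0
            if crowding:
                rot = float(rng.uniform(-6, 6)) * jitter_scale
                dy = float(rng.uniform(-0.7, 0.7)) * jitter_scale
            centre = x + widths[i] / 2.0
            comps.append(_place(tooth, rot, np.array([centre, dy, 0.0])))
            x += widths[i] + gap
        # reject overlapping neighbours (AABB test in the xy plane)
        for a, b in zip(comps[:-1], comps[1:]):
            if a.mesh.vertices[:, 0].max() > b.mesh.vertices[:, 0].min() + 1e-9:
                ok = False
        if ok:
            break
        jitter_scale *= 0.5
    else:
        raise GenerationError("could not place teeth without overlap")

    band_lo = (min(c.mesh.vertices[:, 0].min() for c in comps) - 1.5,
               -max(s.buccolingual for s in specs) / 2 - 2.0, -5.0)
    band_hi = (max(c.mesh.vertices[:, 0].max() for c in comps) + 1.5,
               max(s.buccolingual for s in specs) / 2 + 2.0, -0.8)
    comps.append(ArchComponent("alveolar_band", grid_box(band_lo, band_hi)))
    comps[test_index].name = "test_tooth"
    return comps


def assemble(
    components: list[ArchComponent], test_name: str = "test_tooth"
) -> tuple[TriangleMesh, dict[str, RegionMask], np.ndarray]:
    """Concatenate components into one mesh with global masks and landmarks."""
    mesh = concatenate([c.mesh for c in components])
    offsets = np.cumsum([0] + [c.mesh.n_vertices for c in components])
    labels: dict[str, RegionMask] = {}
    adjacent: list[np.ndarray] = []
    landmarks = None
    for c, off in zip(components, offsets):
        if c.name == test_name:
            for key in ("crown", "buccal", "lingual"):
                labels[key] = RegionMask(key, c.masks[key] + off)
            labels["composite"] = RegionMask(
                "composite", c.masks.get("composite", np.empty(0, dtype=np.int64)) + off
            )
            labels["tooth"] = RegionMask("tooth", np.arange(c.mesh.n_vertices) + off)
            landmarks = np.array(
                [c.landmarks[k] for k in ("tip", "gingival_mid_buccal", "mesial", "distal")]
            )
        elif c.name == "alveolar_band":
            adjacent.append(np.arange(c.mesh.n_vertices) + off)
        else:
            adjacent.append(c.masks["crown"] + off)
            if "composite" in c.masks and len(c.masks["composite"]):
                # a retainer on a neighbour makes part of its crown non-intact
                adjacent[-1] = np.setdiff1d(adjacent[-1], c.masks["composite"] + off)
    if adjacent:
        labels["adjacent_intact"] = RegionMask("adjacent_intact", np.concatenate(adjacent))
    if landmarks is None:
        raise GenerationError(f"no component named {test_name!r}")
    return mesh, labels, landmarks


def generate_arch_segment(
    specs: list[ToothSpec], crowding: bool = False, seed: int = 0
) -> tuple[TriangleMesh, dict[str, RegionMask], np.ndarray]:
    """Watertight arch segment with labels and test-tooth landmarks."""
    return assemble(build_arch_components(specs, crowding=crowding, seed=seed))


# ---------------------------------------------------------------------------
# wear, retainer, noise
# ---------------------------------------------------------------------------

def apply_wear(
    components: list[ArchComponent],
    spec: WearSpec,
    test_name: str = "test_tooth",
    tilt_sign: int = 1,
) -> tuple[list[ArchComponent], float]:
    """Truncate the test tooth's occlusal end; return exact removed volume.

    The cut plane is horizontal for symmetric wear and tilted about the
    mesiodistal axis for asymmetric wear; the removed solid is capped and
    its volume measured, which is exact for the planar construction.
    """
    out = []
    removed_volume = 0.0
    for c in components:
        if c.name != test_name or spec.vertical_loss == 0:
            out.append(copy.deepcopy(c))
            continue
        m = c.mesh
        z_top = float(m.vertices[:, 2].max())
        if spec.vertical_loss >= z_top:
            raise InvalidSpecError("vertical loss must be smaller than the crown height")
        centre = m.vertices.mean(axis=0)
        if spec.pattern == "asymmetric" and spec.tilt_deg > 0:
            alpha = np.deg2rad(spec.tilt_deg) * tilt_sign
            n_up = np.array([0.0, -np.sin(alpha), np.cos(alpha)])
        else:
            n_up = np.array([0.0, 0.0, 1.0])
        point = np.array([centre[0], centre[1], z_top - spec.vertical_loss])
        plane_keep_below = SlicePlane(point, -n_up, "wear_cut")
        plane_keep_above = SlicePlane(point, n_up, "wear_cut")
        below = clip_half_space(m, point, -n_up)
        above = clip_half_space(m, point, n_up)
        if below.n_faces == 0 or above.n_faces == 0:
            raise InvalidSpecError("wear plane does not intersect the tooth")
        worn = close_part(below, [plane_keep_below])
        removed = close_part(above, [plane_keep_above])
        removed_volume = mesh_volume(removed)
        worn_comp = ArchComponent(c.name, worn, {}, copy.deepcopy(c.landmarks))
        # masks must be rebuilt against the new vertex array: the geometric
        # labelling rules are positional, so re-derive them
        v = worn.vertices
        crown = np.nonzero(v[:, 2] > 1e-6)[0]
        local = v - np.array([centre[0], centre[1], 0.0])
        worn_comp.masks = {
            "crown": crown,
            "buccal": crown[local[crown, 1] < 0],
            "lingual": crown[local[crown, 1] >= 0],
        }
        out.append(worn_comp)
    return out, removed_volume


def _retainer_displacement(
    vertices: np.ndarray,
    crown_height: float,
    centre_x: float,
    spec: RetainerSpec,
    blob_jitter: np.ndarray,
) -> np.ndarray:
    """Outward displacement magnitude (mm) of the wire+composite envelope."""
    z_w = spec.wire_height_frac * crown_height
    z = vertices[:, 2]
    r_inf = 2.5 * spec.wire_diameter
    wire = spec.wire_diameter * np.clip(1.0 - ((z - z_w) / r_inf) ** 2, 0.0, None)
    bx, bz, bh = blob_jitter
    rho2 = (vertices[:, 0] - (centre_x + bx)) ** 2 + (z - (z_w + bz)) ** 2
    sigma = spec.blob_radius / 1.5
    blob = (spec.blob_height + bh) * np.exp(-rho2 / (2 * sigma**2))
    return np.minimum(wire + blob, 1.5)


def apply_retainer(
    components: list[ArchComponent],
    spec: RetainerSpec | None,
    seed: int = 0,
    footprint_tol: float = 2e-3,
    params_override: dict[str, tuple[float, float]] | None = None,
) -> list[ArchComponent]:
    """Bond the retainer envelope onto the lingual surfaces of all teeth.

    Lingual crown vertices move outwards along their normals by the
    wire+composite displacement field; every other vertex stays
    bit-identical.  Each tooth gains a ``composite`` mask (its retainer
    footprint).  ``spec=None`` leaves the components unchanged.
    """
    if spec is None:
        return [copy.deepcopy(c) for c in components]
    rng = np.random.default_rng(seed)
    out = []
    for c in components:
        if "lingual" not in c.masks:
            out.append(copy.deepcopy(c))
            continue
        jitter = np.array([rng.uniform(-0.4, 0.4), rng.uniform(-0.2, 0.2), rng.uniform(-0.1, 0.1)])
        m = c.mesh
        v = m.vertices.copy()
        normals = m.vertex_normals()
        if params_override and c.name in params_override:
            # wire height anchored to the original (unworn) crown so the
            # T0 footprint label and the T1 envelope coincide
            crown_h, centre_x = params_override[c.name]
        else:
            crown_h = float(v[:, 2].max())
            centre_x = float(v[:, 0].mean())
        disp = _retainer_displacement(v, crown_h, centre_x, spec, jitter)
        lingual = np.zeros(len(v), dtype=bool)
        lingual[c.masks["lingual"]] = True
        outward = normals[:, 1] > 0.25  # facing the tongue
        active = lingual & outward & (disp > footprint_tol)
        if not active.any():
            raise PlacementError(f"retainer does not reach the lingual surface of {c.name}")
        v[active] += disp[active, None] * normals[active]
        comp = ArchComponent(
            c.name,
            TriangleMesh(v, m.faces.copy()),
            {k: idx.copy() for k, idx in c.masks.items()},
            copy.deepcopy(c.landmarks),
        )
        comp.masks["composite"] = np.nonzero(active)[0]
        out.append(comp)
    return out


def retainer_footprint(
    component: ArchComponent, spec: RetainerSpec, seed: int = 0, footprint_tol: float = 2e-3
) -> np.ndarray:
    """Footprint the retainer would leave on this component (same rule/seed)."""
    masked = apply_retainer([component], spec, seed=seed, footprint_tol=footprint_tol)
    return masked[0].masks["composite"]


def apply_scan_noise(mesh: TriangleMesh, spec: ScanNoiseSpec) -> TriangleMesh:
    """Displace vertices along their normals by clamped Gaussian noise."""
    mesh.validate()
    if spec.sd == 0:
        return mesh.copy()
    rng = np.random.default_rng(spec.seed)
    disp = np.clip(rng.normal(0.0, spec.sd, mesh.n_vertices), -spec.max_dev, spec.max_dev)
    return TriangleMesh(mesh.vertices + disp[:, None] * mesh.vertex_normals(), mesh.faces.copy())


def random_rigid_displacement(
    rng: np.random.Generator, max_rot_deg: float = 15.0, max_trans: float = 10.0
) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.3 * max_rot_deg, max_rot_deg))
    r = Rotation.from_rotvec(axis * angle).as_matrix()
    t = rng.normal(size=3)
    t = t / np.linalg.norm(t) * rng.uniform(0.2 * max_trans, max_trans)
    return RigidTransform(r, t)


# ---------------------------------------------------------------------------
# cases and benchmark
# ---------------------------------------------------------------------------

def _tooth_specs(tooth_type: str, rng: np.random.Generator, resolution: int) -> list[ToothSpec]:
    def one(kind: str, pos: int) -> ToothSpec:
        return ToothSpec(
            tooth_type=kind,
            crown_height=float(rng.uniform(9.2, 10.8)) + (0.8 if kind == "canine" else 0.0),
            mesiodistal=float(rng.uniform(7.2, 8.6)),
            buccolingual=float(rng.uniform(6.4, 7.4)),
            position=pos,
            resolution=resolution,
        )

    flank = "incisor" if tooth_type == "canine" else "incisor"
    return [one(flank, 0), one(tooth_type, 1), one(flank, 2)]


def build_case(
    case_id: str,
    tooth_type: str = "incisor",
    loss: float = 1.0,
    pattern: str = "symmetric",
    crowding: bool = False,
    seed: int = 0,
    resolution: int = 3000,
    noise: ScanNoiseSpec | None = ScanNoiseSpec(),
    retainer: RetainerSpec | None = RetainerSpec(),
    landmark_sd: float = 0.15,
) -> WearCase:
    """Generate one complete synthetic case (T0, T1, labels, ground truth)."""
    rng = np.random.default_rng(seed)
    specs = _tooth_specs(tooth_type, rng, resolution)
    comps0 = build_arch_components(specs, crowding=crowding, seed=int(rng.integers(2**31 - 1)))

    wear = WearSpec(loss, pattern, tilt_deg=float(rng.uniform(6, 14)))
    tilt_sign = 1 if rng.random() < 0.5 else -1
    comps1, removed = apply_wear(comps0, wear, tilt_sign=tilt_sign)
    retainer_seed = int(rng.integers(2**31 - 1))
    overrides = {
        c.name: (float(c.mesh.vertices[:, 2].max()), float(c.mesh.vertices[:, 0].mean()))
        for c in comps0
        if "lingual" in c.masks
    }
    comps1 = apply_retainer(comps1, retainer, seed=retainer_seed, params_override=overrides)
    if retainer is not None:
        # the composite footprint label lives on T0: same displacement rule,
        # same seed sequence, applied to the original geometry
        comps0 = [copy.deepcopy(c) for c in comps0]
        footprints = apply_retainer(comps0, retainer, seed=retainer_seed,
                                    params_override=overrides)
        for c0, cf in zip(comps0, footprints):
            if "composite" in cf.masks:
                c0.masks["composite"] = cf.masks["composite"]

    t0_mesh, labels, lm0 = assemble(comps0)
    t1_mesh, labels1, lm1 = assemble(comps1)

    if noise is not None:
        t0_mesh = apply_scan_noise(t0_mesh, replace(noise, seed=int(rng.integers(2**31 - 1))))
        t1_mesh = apply_scan_noise(t1_mesh, replace(noise, seed=int(rng.integers(2**31 - 1))))

    pose = random_rigid_displacement(rng)
    t1_mesh = t1_mesh.transformed(pose)
    lm1 = pose.apply(lm1) + rng.normal(0.0, landmark_sd, size=lm1.shape)

    labels = dict(labels)
    labels["tooth_t1"] = RegionMask("tooth_t1", labels1["tooth"].indices)
    return WearCase(
        case_id=case_id,
        t0_model=t0_mesh,
        t1_model=t1_mesh,
        labels=labels,
        landmarks=(lm0, lm1),
        true_removed_volume=removed,
        tooth_type=tooth_type,
        loss_level=loss,
        pattern=pattern,
        crowding=crowding,
        seed=seed,
    )


def build_benchmark(
    n_incisors: int = 18,
    n_canines: int = 18,
    loss_levels: tuple[float, ...] = (0.5, 1.0, 2.0),
    patterns: tuple[str, ...] = ("symmetric", "asymmetric"),
    crowding_mix: bool = True,
    seed: int = 0,
    resolution: int = 3000,
    noise: ScanNoiseSpec | None = ScanNoiseSpec(),
    retainer: RetainerSpec | None = RetainerSpec(),
) -> list[WearCase]:
    """Balanced benchmark: tooth types × loss levels × patterns × crowding."""
    if min(n_incisors, n_canines) < 1:
        raise InvalidSpecError("need at least one tooth per type")
    rng = np.random.default_rng(seed)
    cases = []
    counter = 0
    for tooth_type, n in (("incisor", n_incisors), ("canine", n_canines)):
        for k in range(n):
            loss = loss_levels[k % len(loss_levels)]
            pattern = patterns[(k // len(loss_levels)) % len(patterns)]
            crowding = bool(k % 2) if crowding_mix else False
            counter += 1
            cases.append(
                build_case(
                    case_id=f"case_{counter:03d}_{tooth_type}",
                    tooth_type=tooth_type,
                    loss=loss,
                    pattern=pattern,
                    crowding=crowding,
                    seed=int(rng.integers(2**31 - 1)),
                    resolution=resolution,
                    noise=noise,
                    retainer=retainer,
                )
            )
    return cases


def manifest(cases: list[WearCase]) -> pd.DataFrame:
    """Tabular description of a benchmark (one row per case)."""
    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "tooth_type": [c.tooth_type for c in cases],
            "loss_level": [c.loss_level for c in cases],
            "pattern": [c.pattern for c in cases],
            "crowding": [c.crowding for c in cases],
            "seed": [c.seed for c in cases],
            "true_removed_volume": [c.true_removed_volume for c in cases],
        }
    )
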