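"""Mesh data model, STL/PLY I/O, topology queries and watertight volumes.

All geometry is in millimetres, right-handed coordinates, with faces wound
counter-clockwise when seen from outside.  The :class:`TriangleMesh` is the
single carrier of geometry through the whole pipeline; it deliberately stays
a thin indexed triangle soup with a few cached topology queries, so every
downstream operation (registration, slicing, volumetrics) states its own
preconditions explicitly instead of relying on hidden repair steps.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .errors import (
    DegenerateInputError,
    InvalidInputError,
    MeshFormatError,
    TopologyError,
)

log = logging.getLogger(__name__)

#: Exact-duplicate weld tolerance (mm).  STL stores a triangle soup, so
#: coincident corner vertices must be merged; the tolerance is kept tiny to
#: avoid accidentally merging fine retainer-wire geometry.
WELD_TOL = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """Indexed triangle surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm.
    faces : (m, 3) int array of 0-based vertex indices, outward orientation.
    vertex_scalar : optional (n,) float array, a per-vertex field in mm
        (used for signed distance maps).
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_scalar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertex_scalar is not None:
            self.vertex_scalar = np.asarray(self.vertex_scalar, dtype=np.float64)

    # -- validation ---------------------------------------------------------
    def validate(self) -> "TriangleMesh":
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise InvalidInputError("mesh has no vertices or no faces")
        if not np.isfinite(self.vertices).all():
            raise InvalidInputError("mesh has non-finite coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise InvalidInputError("face index out of range")
        if (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise InvalidInputError("degenerate face (repeated vertex index)")
        if self.vertex_scalar is not None and len(self.vertex_scalar) != len(self.vertices):
            raise InvalidInputError("vertex_scalar length mismatch")
        return self

    # -- small conveniences -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, unit: bool = True) -> np.ndarray:
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        if unit:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit)."""
        fn = self.face_normals(unit=False)  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_scalar is None else self.vertex_scalar.copy(),
        )

    def transformed(self, transform: "RigidTransform") -> "TriangleMesh":
        return TriangleMesh(
            transform.apply(self.vertices),
            self.faces.copy(),
            None if self.vertex_scalar is None else self.vertex_scalar.copy(),
        )

    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])


@dataclass
class RegionMask:
    """A named vertex subset of a specific mesh (reference area / label)."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        self.indices = idx

    def validate(self, mesh: TriangleMesh) -> "RegionMask":
        if len(self.indices) == 0:
            raise InvalidInputError(f"region mask {self.name!r} is empty")
        if self.indices.min() < 0 or self.indices.max() >= mesh.n_vertices:
            raise InvalidInputError(f"region mask {self.name!r} has out-of-range indices")
        return self


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation; maps points of a source frame into a target frame."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=np.float64).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=np.float64).reshape(3))
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(r), 1.0, atol=1e-9
        ):
            raise DegenerateInputError("rotation is not a proper orthonormal matrix")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors, dtype=np.float64) @ self.rotation.T

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return self ∘ first (apply ``first``, then ``self``)."""
        return RigidTransform(self.rotation @ first.rotation,
                              self.rotation @ first.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def save(self, path: str | Path) -> None:
        np.savetxt(path, self.matrix(), fmt="%.17g")

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path))


# ---------------------------------------------------------------------------
# welding and cleanup
# ---------------------------------------------------------------------------

def weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` (exact-duplicate welding).

    Coordinates are quantised onto a ``tol`` grid; identical cells merge.
    Idempotent for tol below half the smallest true vertex separation.
    """
    keys = np.round(np.asarray(vertices, dtype=np.float64) / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    new_vertices = vertices[np.sort(first)]
    # re-map so vertex order follows first appearance (deterministic)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_faces = rank[inverse][faces]
    return new_vertices, new_faces


def drop_degenerate_faces(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Remove faces with repeated indices or (numerically) zero area."""
    f = faces
    good = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    t = vertices[f]
    area2 = np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
    good &= area2 > 0.0
    dropped = int((~good).sum())
    if dropped:
        log.info("dropped %d degenerate faces at load", dropped)
    return f[good]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = {"stl_binary", "stl_ascii", "stl", "ply"}


def load_mesh(path: str | Path, format: str | None = None) -> TriangleMesh:
    """Load an STL (binary/ASCII) or PLY mesh, weld duplicates, drop degenerates.

    PLY files written by :func:`save_scalar_field` restore the per-vertex
    ``quality`` field into :attr:`TriangleMesh.vertex_scalar`.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    fmt = format or ("ply" if path.suffix.lower() == ".ply" else "stl")
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported format {fmt!r}")
    if fmt == "ply":
        vertices, faces, scalar = _read_ply(path)
    else:
        try:
            tm = _trimesh.load(str(path), file_type="stl", process=False)
        except Exception as exc:  # pragma: no cover - corrupt file path
            raise MeshFormatError(f"cannot read {path}: {exc}") from exc
        if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
            raise InvalidInputError(f"{path} contains no triangles")
        vertices, faces, scalar = np.asarray(tm.vertices, float), np.asarray(tm.faces), None
    if len(faces) == 0:
        raise InvalidInputError(f"{path} contains no triangles")
    vertices, faces = weld_vertices(vertices, faces)
    faces = drop_degenerate_faces(vertices, faces)
    mesh = TriangleMesh(vertices, faces, scalar)
    return mesh.validate()


def save_mesh(mesh: TriangleMesh, path: str | Path, format: str = "stl_binary") -> None:
    """Write ``mesh`` as binary/ASCII STL or ASCII PLY (no watertight requirement)."""
    path = Path(path)
    if format in ("stl_binary", "stl"):
        _write_stl_binary(mesh, path)
    elif format == "stl_ascii":
        tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        path.write_text(tm.export(file_type="stl_ascii"))
    elif format == "ply":
        _write_ply(mesh, path, scalar=None)
    else:
        raise MeshFormatError(f"unsupported format {format!r}")


def save_scalar_field(mesh: TriangleMesh, path: str | Path) -> None:
    """Write an ASCII PLY carrying the per-vertex ``quality`` scalar (mm)."""
    if mesh.vertex_scalar is None:
        raise InvalidInputError("mesh has no vertex scalar field to save")
    _write_ply(mesh, Path(path), scalar=mesh.vertex_scalar)


def _write_stl_binary(mesh: TriangleMesh, path: Path) -> None:
    tri = mesh.triangles().astype("<f4")
    normals = mesh.face_normals().astype("<f4")
    n = len(tri)
    rec = np.zeros(n, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")])
    rec["n"] = normals
    rec["v"] = tri
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 80)
        fh.write(struct.pack("<I", n))
        fh.write(rec.tobytes())


def _write_ply(mesh: TriangleMesh, path: Path, scalar: np.ndarray | None) -> None:
    props = ["property double x", "property double y", "property double z"]
    if scalar is not None:
        props.append("property double quality")
    header = "\n".join(
        [
            "ply",
            "format ascii 1.0",
            f"element vertex {mesh.n_vertices}",
            *props,
            f"element face {mesh.n_faces}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
    )
    lines = [header]
    cols = mesh.vertices if scalar is None else np.column_stack([mesh.vertices, scalar])
    for row in cols:
        lines.append(" ".join(f"{v:.17g}" for v in row))
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    try:
        text = path.read_text().splitlines()
    except UnicodeDecodeError:
        # binary PLY: delegate to trimesh
        tm = _trimesh.load(str(path), file_type="ply", process=False)
        return np.asarray(tm.vertices, float), np.asarray(tm.faces), None
    if not text or text[0].strip() != "ply":
        raise MeshFormatError(f"{path} is not a PLY file")
    n_vert = n_face = 0
    vprops: list[str] = []
    i = 1
    element = None
    while i < len(text):
        tok = text[i].split()
        i += 1
        if not tok:
            continue
        if tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n_vert = int(tok[2])
            elif element == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
            vprops.append(tok[-1])
        elif tok[0] == "end_header":
            break
    data = np.array([[float(v) for v in text[i + k].split()] for k in range(n_vert)])
    faces = []
    for k in range(n_face):
        tok = text[i + n_vert + k].split()
        if int(tok[0]) != 3:
            raise MeshFormatError("only triangle PLY faces are supported")
        faces.append([int(tok[1]), int(tok[2]), int(tok[3])])
    cols = {p: data[:, j] for j, p in enumerate(vprops)}
    vertices = np.column_stack([cols["x"], cols["y"], cols["z"]])
    scalar = cols.get("quality")
    return vertices, np.asarray(faces, dtype=np.int64), scalar


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def _directed_edges(mesh: TriangleMesh) -> np.ndarray:
    f = mesh.faces
    return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])


def edge_face_incidence(mesh: TriangleMesh) -> dict[tuple[int, int], int]:
    """Count of incident faces per undirected edge."""
    e = _directed_edges(mesh)
    und = np.sort(e, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    return {tuple(k): int(c) for k, c in zip(uniq, counts)}


def is_watertight(mesh: TriangleMesh) -> bool:
    """True iff every edge is shared by exactly two faces with opposite traversal.

    Disjoint closed components count as watertight (the per-edge condition is
    local), matching how a multi-tooth scene is handled.
    """
    e = _directed_edges(mesh)
    # no duplicated directed edge, and every directed edge has its reverse
    d = {}
    for a, b in e:
        key = (int(a), int(b))
        if key in d:
            return False
        d[key] = True
    return all((b, a) in d for (a, b) in d)


def boundary_edges(mesh: TriangleMesh) -> np.ndarray:
    """Directed boundary edges (oriented as they appear in their single face)."""
    e = _directed_edges(mesh)
    und = np.sort(e, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    if (counts > 2).any():
        raise TopologyError("non-manifold edge (more than two incident faces)")
    return e[counts[inv] == 1]


def boundary_loops(mesh: TriangleMesh) -> list[np.ndarray]:
    """Ordered closed cycles of boundary vertices.

    Each loop follows the directed boundary edges, i.e. it runs in the same
    sense as the winding of the adjacent faces; a cap built on the *reversed*
    loop therefore continues the outward orientation.
    """
    edges = boundary_edges(mesh)
    if len(edges) == 0:
        return []
    nxt: dict[int, int] = {}
    for a, b in edges:
        a, b = int(a), int(b)
        if a in nxt:
            raise TopologyError("non-manifold boundary vertex (branching boundary)")
        nxt[a] = b
    loops = []
    seen: set[int] = set()
    for start in sorted(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            if cur in seen or cur not in nxt:
                raise TopologyError("boundary edges do not close into loops")
            loop.append(cur)
            seen.add(cur)
            cur = nxt[cur]
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (mm³) of a watertight, outward-oriented mesh.

    Divergence theorem: sum of signed tetrahedra spanned with the origin;
    translation invariant for closed surfaces.  Multi-component meshes give
    the sum of component volumes.
    """
    if not is_watertight(mesh):
        raise TopologyError("mesh_volume requires a watertight mesh")
    t = mesh.triangles()
    return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)


def submesh(mesh: TriangleMesh, vertex_indices: np.ndarray) -> tuple[TriangleMesh, np.ndarray]:
    """Faces whose three corners all lie in ``vertex_indices``, reindexed.

    Returns the submesh and the array of original vertex ids for each new
    vertex (new → old map).
    """
    keep = np.zeros(mesh.n_vertices, dtype=bool)
    keep[np.asarray(vertex_indices, dtype=np.int64)] = True
    fmask = keep[mesh.faces].all(axis=1)
    faces = mesh.faces[fmask]
    if len(faces) == 0:
        raise InvalidInputError("submesh selects no complete faces")
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sm = TriangleMesh(mesh.vertices[used], remap[faces])
    if mesh.vertex_scalar is not None:
        sm.vertex_scalar = mesh.vertex_scalar[used]
    return sm, used


def connected_vertex_components(mesh: TriangleMesh) -> np.ndarray:
    """Component label per vertex (faces define adjacency)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    e = _directed_edges(mesh)
    n = mesh.n_vertices
    adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def concatenate(meshes: list[TriangleMesh]) -> TriangleMesh:
    """Stack meshes into one (disjoint components; indices offset)."""
    vs, fs, off = [], [], 0
    for m in meshes:
        vs.append(m.vertices)
        fs.append(m.faces + off)
        off += m.n_vertices
    return TriangleMesh(np.vstack(vs), np.vstack(fs))
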