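"""Mesh model, I/O, topology and volume."""

import numpy as np
import pytest
import trimesh as _trimesh
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from toothwear.core import (
    RegionMask,
    RigidTransform,
    TriangleMesh,
    boundary_loops,
    is_watertight,
    load_mesh,
    mesh_volume,
    save_mesh,
    save_scalar_field,
    submesh,
    weld_vertices,
)
from toothwear.errors import (
    DegenerateInputError,
    InvalidInputError,
    MeshFormatError,
    TopologyError,
)

from conftest import to_mesh


# ---------------------------------------------------------------------------
# I/O and welding
# ---------------------------------------------------------------------------

class TestLoadSave:
    def test_stl_round_trip_welds_cube_soup(self, cube, tmp_path):
        # STL stores a triangle soup (36 raw vertices for a cube); loading
        # must weld exact duplicates back to 8 vertices / 12 faces
        path = tmp_path / "cube.stl"
        save_mesh(cube, path, "stl_binary")
        again = load_mesh(path)
        assert again.n_vertices == 8
        assert again.n_faces == 12
        # brute-force oracle: count distinct coordinate triples of the soup
        soup = cube.triangles().reshape(-1, 3)
        assert len(np.unique(np.round(soup / 1e-9).astype(np.int64), axis=0)) == 8
        assert mesh_volume(again) == pytest.approx(1.0, abs=1e-12)

    def test_stl_ascii_round_trip(self, cube, tmp_path):
        path = tmp_path / "cube_ascii.stl"
        save_mesh(cube, path, "stl_ascii")
        again = load_mesh(path, format="stl_ascii")
        assert mesh_volume(again) == pytest.approx(1.0, rel=1e-6)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.stl"
        tm = _trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3)))
        path.write_bytes(tm.export(file_type="stl"))
        with pytest.raises(InvalidInputError):
            load_mesh(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(MeshFormatError):
            load_mesh(tmp_path / "nope.stl")

    def test_scalar_field_ply_round_trip(self, cube, tmp_path):
        cube.vertex_scalar = np.linspace(-0.4, 0.7, cube.n_vertices)
        path = tmp_path / "field.ply"
        save_scalar_field(cube, path)
        again = load_mesh(path, format="ply")
        assert again.vertex_scalar is not None
        assert np.abs(np.sort(again.vertex_scalar) - np.sort(cube.vertex_scalar)).max() < 1e-6
        assert np.abs(again.vertices - cube.vertices).max() < 1e-12

    def test_open_mesh_saves_fine(self, cube, tmp_path):
        open_mesh = TriangleMesh(cube.vertices, cube.faces[:-2])
        save_mesh(open_mesh, tmp_path / "open.stl")
        assert load_mesh(tmp_path / "open.stl").n_faces == 10

    def test_weld_is_idempotent(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-1, 1, (30, 3))
        soup = np.vstack([v, v[:10]])
        faces = np.arange(39).reshape(13, 3)
        v1, f1 = weld_vertices(soup, faces)
        v2, f2 = weld_vertices(v1, f1)
        assert np.array_equal(v1, v2) and np.array_equal(f1, f2)
        assert len(v1) == 30


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

class TestTopology:
    def test_closed_cube_watertight_no_loops(self, cube):
        assert is_watertight(cube)
        assert boundary_loops(cube) == []

    def test_cube_with_missing_face_is_open(self, cube):
        open_mesh = TriangleMesh(cube.vertices, cube.faces[:-1])
        assert not is_watertight(open_mesh)
        assert len(boundary_loops(open_mesh)) == 1

    def test_two_disjoint_cubes_watertight(self, cube):
        shifted = TriangleMesh(cube.vertices + 5.0, cube.faces + cube.n_vertices)
        both = TriangleMesh(
            np.vstack([cube.vertices, shifted.vertices]),
            np.vstack([cube.faces, shifted.faces]),
        )
        assert is_watertight(both)
        assert mesh_volume(both) == pytest.approx(2.0, abs=1e-12)

    def test_cube_missing_quad_gives_4_vertex_loop(self, cube):
        # remove the two triangles of the z=top quad
        top = cube.faces[
            ~(np.isclose(cube.vertices[cube.faces, 2], 1.0).all(axis=1))
        ]
        open_mesh = TriangleMesh(cube.vertices, top)
        loops = boundary_loops(open_mesh)
        assert len(loops) == 1
        assert len(loops[0]) == 4

    def test_open_cylinder_has_two_loops(self):
        # tube without caps; oracle: brute-force edge incidence scan
        n = 24
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        ring = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
        verts = np.vstack([ring, ring + [0, 0, 2.0]])
        faces = []
        for j in range(n):
            j2 = (j + 1) % n
            faces.append((j, j2, n + j2))
            faces.append((j, n + j2, n + j))
        cyl = TriangleMesh(verts, np.asarray(faces))
        edges = np.sort(
            np.concatenate([cyl.faces[:, [0, 1]], cyl.faces[:, [1, 2]], cyl.faces[:, [2, 0]]]),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert (counts == 1).sum() == 2 * n  # brute-force boundary edge count
        loops = boundary_loops(cyl)
        assert len(loops) == 2
        assert sorted(len(l) for l in loops) == [n, n]

    def test_nonmanifold_edge_rejected(self, cube):
        extra = np.vstack([cube.faces, [[0, 1, 2]], [[0, 1, 4]], [[0, 1, 6]]])
        with pytest.raises(TopologyError):
            boundary_loops(TriangleMesh(cube.vertices, extra))


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------

class TestVolume:
    def test_cube_volume_exact(self, cube):
        assert mesh_volume(cube) == pytest.approx(1.0, abs=1e-14)

    def test_translation_invariance(self, cube):
        far = TriangleMesh(cube.vertices + np.array([100.0, -50.0, 7.0]), cube.faces)
        assert mesh_volume(far) == pytest.approx(1.0, abs=1e-9)

    def test_icosphere_close_to_analytic_and_hull(self, icosphere):
        from scipy.spatial import ConvexHull

        v = mesh_volume(icosphere)
        assert v == pytest.approx(4 * np.pi / 3, rel=0.01)
        # independent oracle: convex-hull volume of the same vertex set
        assert v == pytest.approx(ConvexHull(icosphere.vertices).volume, rel=1e-9)

    def test_open_mesh_rejected(self, cube):
        with pytest.raises(TopologyError):
            mesh_volume(TriangleMesh(cube.vertices, cube.faces[:-1]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        tm = _trimesh.creation.box(extents=rng.uniform(0.5, 3.0, 3))
        mesh = to_mesh(tm)
        r = Rotation.random(random_state=int(seed)).as_matrix()
        t = RigidTransform(r, rng.uniform(-10, 10, 3))
        v0, v1 = mesh_volume(mesh), mesh_volume(mesh.transformed(t))
        assert abs(v1 - v0) < 1e-9 * max(1.0, abs(v0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class TestDomainTypes:
    def test_rigid_transform_validates_rotation(self):
        with pytest.raises(DegenerateInputError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_rigid_transform_compose_inverse(self):
        rng = np.random.default_rng(3)
        a = RigidTransform(Rotation.random(random_state=1).as_matrix(), rng.normal(size=3))
        b = RigidTransform(Rotation.random(random_state=2).as_matrix(), rng.normal(size=3))
        pts = rng.normal(size=(5, 3))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))
        assert np.allclose(a.inverse().apply(a.apply(pts)), pts, atol=1e-12)

    def test_transform_file_round_trip(self, tmp_path):
        t = RigidTransform(Rotation.random(random_state=7).as_matrix(), [1.0, -2.0, 0.5])
        t.save(tmp_path / "t.txt")
        again = RigidTransform.load(tmp_path / "t.txt")
        assert np.allclose(again.matrix(), t.matrix())

    def test_region_mask_validation(self, cube):
        with pytest.raises(InvalidInputError):
            RegionMask("empty", np.array([], dtype=int)).validate(cube)
        with pytest.raises(InvalidInputError):
            RegionMask("oob", np.array([99])).validate(cube)

    def test_submesh_reindexes(self, cube):
        bottom = np.nonzero(cube.vertices[:, 2] < 0.5)[0]
        sm, used = submesh(cube, bottom)
        assert sm.n_vertices == len(used) == 4
        assert np.allclose(cube.vertices[used], sm.vertices)
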