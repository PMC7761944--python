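"""Slicing, hole splitting/filling and wear-volume measurement."""

import numpy as np
import pytest

from toothwear.core import (
    TriangleMesh,
    boundary_loops,
    is_watertight,
    mesh_volume,
    submesh,
)
from toothwear.errors import CannotIsolateError, EmptyPartError, GeometryError
from toothwear.synthetic import grid_box
from toothwear.wear import (
    SlicePlane,
    close_part,
    distance_map,
    fill_holes,
    measure_wear,
    propose_slice_planes,
    slice_with_planes,
    sliced_volume_difference,
    split_hole,
)

from test_geometry import square_patch


class TestDistanceMap:
    def test_identical_meshes_give_zero(self, cube):
        d = distance_map(cube, cube)
        assert np.abs(d).max() < 1e-12

    def test_parallel_planes_offset(self):
        lower = square_patch()
        raised = square_patch()
        raised = TriangleMesh(raised.vertices + [0, 0, 0.5], raised.faces)
        d = distance_map(raised, lower)  # source above target, normals +z
        assert np.allclose(d, 0.5, atol=1e-12)

    def test_worn_tooth_peak_matches_nominal_loss(self, case_noisefree):
        # noise-free, so the GS alignment is exact: the deepest point of the
        # map must sit near the 1 mm nominal vertical loss
        t0_tooth, _ = submesh(case_noisefree.t0_model, case_noisefree.labels["tooth"].indices)
        t1_tooth, _ = submesh(case_noisefree.t1_model, case_noisefree.labels["tooth_t1"].indices)
        meas, art = measure_wear(
            case_noisefree.t0_model, case_noisefree.t1_model, case_noisefree.labels,
            "GS", case_noisefree.landmarks, seed=0, return_artifacts=True,
        )
        peak = np.abs(art["distance_map"].vertex_scalar).max()
        assert peak == pytest.approx(1.0, rel=0.10)


class TestSlicing:
    def test_cube_sliced_at_half(self, cube):
        plane = SlicePlane((0, 0, 0.5), (0, 0, 1))
        part = slice_with_planes(cube, [plane])
        capped = close_part(part, [plane])
        assert is_watertight(capped)
        assert mesh_volume(capped) == pytest.approx(0.5, abs=1e-12)

    def test_plane_missing_mesh_is_empty_part(self, cube):
        with pytest.raises(EmptyPartError):
            slice_with_planes(cube, [SlicePlane((0, 0, 1.5), (0, 0, 1))])

    def test_conservation_on_tooth(self, case_noisefree):
        tooth, _ = submesh(case_noisefree.t0_model, case_noisefree.labels["tooth"].indices)
        up = SlicePlane((0, 0, 5.0), (0, 0, 1))
        dn = SlicePlane((0, 0, 5.0), (0, 0, -1))
        v_up = mesh_volume(close_part(slice_with_planes(tooth, [up]), [up]))
        v_dn = mesh_volume(close_part(slice_with_planes(tooth, [dn]), [dn]))
        assert v_up + v_dn == pytest.approx(mesh_volume(tooth), rel=1e-9)


class TestSplitHole:
    def test_single_plane_loop_unchanged(self, cube):
        plane = SlicePlane((0, 0, 0.5), (0, 0, 1))
        part = slice_with_planes(cube, [plane])
        (loop,) = boundary_loops(part)
        out = split_hole(part, loop, [plane])
        assert len(out) == 1
        assert np.array_equal(out[0], loop)

    def test_l_prism_two_plane_split(self):
        # box cut by two orthogonal planes leaves an L-shaped part whose
        # hole spans both planes; the split must give two planar loops with
        # the chord on the planes' intersection line
        box = grid_box((0, 0, 0), (4, 4, 4), cell=4.0)
        planes = [
            SlicePlane((0, 0, 2.0), (0, 0, -1), "gingival"),   # keep z <= 2
            SlicePlane((2.0, 0, 0), (-1, 0, 0), "distal"),     # keep x <= 2
        ]
        part = slice_with_planes(box, planes)
        loops = boundary_loops(part)
        assert len(loops) == 1
        pieces = split_hole(part, loops[0], planes)
        assert len(pieces) == 2
        # each piece planar on one of the planes
        for piece in pieces:
            pts = part.vertices[piece]
            on_z = np.abs(pts[:, 2] - 2.0).max() < 1e-6
            on_x = np.abs(pts[:, 0] - 2.0).max() < 1e-6
            assert on_z or on_x
        capped = fill_holes(part, pieces)
        assert is_watertight(capped)
        # manual decomposition: the kept solid is the 2x4x2 slab plus nothing
        # else (intersection of two half-spaces of the 4-cube)
        assert mesh_volume(capped) == pytest.approx(2 * 4 * 2, abs=1e-9)

    def test_gingival_plus_mesial_and_distal_planes(self):
        # one occlusal plane plus two proximal planes cutting clear across:
        # each crease carries exactly two contralateral loop vertices, so
        # the hole splits into three planar pieces
        box = grid_box((0, 0, 0), (4, 4, 4), cell=4.0)
        planes = [
            SlicePlane((0, 0, 3.0), (0, 0, -1), "gingival"),
            SlicePlane((1.0, 0, 0), (1, 0, 0), "mesial"),
            SlicePlane((3.0, 0, 0), (-1, 0, 0), "distal"),
        ]
        part = slice_with_planes(box, planes)
        (loop,) = boundary_loops(part)
        pieces = split_hole(part, loop, planes)
        assert len(pieces) == 3
        capped = fill_holes(part, pieces)
        assert is_watertight(capped)
        assert mesh_volume(capped) == pytest.approx(2 * 4 * 3, abs=1e-9)


class TestFillHoles:
    def test_half_cube_watertight(self, cube):
        plane = SlicePlane((0, 0, 0.25), (0, 0, 1))
        part = slice_with_planes(cube, [plane])
        loops = boundary_loops(part)
        capped = fill_holes(part, loops)
        assert is_watertight(capped)
        assert mesh_volume(capped) == pytest.approx(0.75, abs=1e-12)

    def test_cap_triangulation_independent_volume(self, icosphere):
        plane = SlicePlane((0, 0, 0.1), (0, 0, 1))
        part = slice_with_planes(icosphere, [plane])
        (loop,) = boundary_loops(part)
        v1 = mesh_volume(fill_holes(part, [loop]))
        # a different (rotated) traversal of the same planar polygon yields a
        # different triangulation of the cap but must give the same volume
        rotated = np.roll(loop, 7)
        v2 = mesh_volume(fill_holes(part, [rotated]))
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_figure_eight_loop_rejected(self):
        verts = np.array(
            [[0, 0, 0], [1, 1, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 1.0]], dtype=float
        )
        part = TriangleMesh(verts, np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]]))
        with pytest.raises(GeometryError):
            fill_holes(part, [np.array([0, 1, 2, 3])])


class TestProposePlanes:
    def test_unchanged_pair_defaults_to_mid_crown(self, cube):
        planes, d = propose_slice_planes(cube, cube, gingival_limit=0.0)
        assert len(planes) == 1
        assert planes[0].role == "gingival"
        assert 0.2 < planes[0].point[2] < 0.8

    def test_wear_to_the_gingival_margin_cannot_be_isolated(self, cube):
        # the whole upper surface moved and the crown region offers no
        # unchanged band for a cut: no admissible plane remains
        worn = TriangleMesh(cube.vertices.copy(), cube.faces)
        worn.vertices[:, 2] *= 0.1  # crush essentially the full height
        with pytest.raises(CannotIsolateError):
            propose_slice_planes(cube, worn, gingival_limit=0.05)

    def test_plane_sits_below_changed_region(self, case_noisefree):
        meas = measure_wear(
            case_noisefree.t0_model, case_noisefree.t1_model, case_noisefree.labels,
            "GS", case_noisefree.landmarks, seed=0,
        )
        (plane,) = meas.planes
        t0_tooth, _ = submesh(case_noisefree.t0_model, case_noisefree.labels["tooth"].indices)
        top = t0_tooth.vertices[:, 2].max()
        assert plane.point[2] < top - 1.0  # below the 1 mm wear zone


class TestMeasureWear:
    def test_unchanged_pair_measures_zero(self, unchanged_pair):
        meas = measure_wear(
            unchanged_pair.t0_model, unchanged_pair.t1_model, unchanged_pair.labels,
            "CC_C", unchanged_pair.landmarks, seed=0,
        )
        assert abs(meas.wear_volume) < 0.005

    def test_gs_recovers_ground_truth_noise_free(self, case_noisefree):
        meas = measure_wear(
            case_noisefree.t0_model, case_noisefree.t1_model, case_noisefree.labels,
            "GS", case_noisefree.landmarks, seed=0,
        )
        assert meas.wear_volume == pytest.approx(case_noisefree.true_removed_volume, rel=0.02)
        assert meas.wear_volume == pytest.approx(
            meas.t0_part_volume - meas.t1_part_volume, abs=1e-12
        )

    def test_swapping_models_negates_wear(self, case_noisefree):
        t0_tooth, _ = submesh(case_noisefree.t0_model, case_noisefree.labels["tooth"].indices)
        t1_tooth, _ = submesh(case_noisefree.t1_model, case_noisefree.labels["tooth_t1"].indices)
        meas = measure_wear(
            case_noisefree.t0_model, case_noisefree.t1_model, case_noisefree.labels,
            "GS", case_noisefree.landmarks, seed=0,
        )
        t1a = t1_tooth.transformed(meas.transform)
        v0, v1, w = sliced_volume_difference(t0_tooth, t1a, meas.planes)
        v1b, v0b, wb = sliced_volume_difference(t1a, t0_tooth, meas.planes)
        assert wb == pytest.approx(-w, abs=1e-12)

    def test_plane_position_insensitivity(self, case_noisefree):
        # moving the gingival plane 0.2 mm gingivally adds identical slabs
        # to both parts: the wear volume must barely move
        t0_tooth, _ = submesh(case_noisefree.t0_model, case_noisefree.labels["tooth"].indices)
        t1_tooth, _ = submesh(case_noisefree.t1_model, case_noisefree.labels["tooth_t1"].indices)
        meas = measure_wear(
            case_noisefree.t0_model, case_noisefree.t1_model, case_noisefree.labels,
            "GS", case_noisefree.landmarks, seed=0,
        )
        t1a = t1_tooth.transformed(meas.transform)
        (plane,) = meas.planes
        moved = SlicePlane(plane.point - [0, 0, 0.2], plane.normal, plane.role)
        *_, w1 = sliced_volume_difference(t0_tooth, t1a, [plane])
        *_, w2 = sliced_volume_difference(t0_tooth, t1a, [moved])
        assert abs(w2 - w1) / abs(w1) < 0.005
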