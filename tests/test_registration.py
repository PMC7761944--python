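"""Trimmed ICP registration: coarse fit, correspondences, trimming, staging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from toothwear.core import RegionMask, RigidTransform
from toothwear.errors import DegenerateInputError, InvalidInputError
from toothwear.registration import (
    ICPSettings,
    coarse_align,
    find_correspondences,
    icp_register,
    optimize_overlap_fraction,
    staged_register,
    trim_correspondences,
)
from toothwear.synthetic import ToothSpec, make_tooth

from test_geometry import square_patch


@pytest.fixture(scope="module")
def tooth():
    return make_tooth(ToothSpec(resolution=900), seed=5)


def random_rigid(seed, max_deg=10.0, max_t=5.0):
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    r = Rotation.from_rotvec(axis * np.deg2rad(rng.uniform(1, max_deg))).as_matrix()
    return RigidTransform(r, rng.uniform(-max_t, max_t, 3))


class TestCoarseAlign:
    def test_recovers_known_transform(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(-5, 5, (4, 3))
        truth = RigidTransform(
            Rotation.from_euler("z", 10, degrees=True).as_matrix(), [1.0, 2.0, 3.0]
        )
        est = coarse_align(src, truth.apply(src))
        assert np.abs(est.apply(src) - truth.apply(src)).max() < 1e-9

    def test_identity_for_identical_sets(self):
        pts = np.random.default_rng(2).normal(size=(5, 3))
        est = coarse_align(pts, pts)
        assert np.allclose(est.matrix(), np.eye(4), atol=1e-12)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(4.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            coarse_align(line, line)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DegenerateInputError):
            coarse_align(np.zeros((2, 3)), np.zeros((2, 3)))


class TestCorrespondences:
    def test_closest_point_on_plane(self):
        idx, pts, dist, normals = find_correspondences(
            np.array([[0.3, 0.3, 1.0]]), square_patch(), exclude_overhangs=False
        )
        assert dist[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(pts[0], [0.3, 0.3, 0.0])
        assert np.allclose(np.abs(normals[0]), [0, 0, 1])

    def test_overhang_pairs_discarded(self):
        idx, *_ = find_correspondences(
            np.array([[0.5, 0.5, 0.2], [2.0, 0.5, 0.2]]), square_patch(), True
        )
        assert list(idx) == [0]

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            find_correspondences(np.zeros((0, 3)), square_patch(), False)


class TestTrim:
    def test_keeps_smallest_fraction(self):
        d = np.arange(1.0, 11.0)[::-1]  # 10..1
        kept = trim_correspondences(d, 0.4)
        assert sorted(d[kept]) == [1, 2, 3, 4]

    def test_full_fraction_keeps_all(self):
        assert len(trim_correspondences(np.arange(7.0), 1.0)) == 7

    def test_ties_break_by_source_order(self):
        d = np.ones(9)
        kept = trim_correspondences(d, 0.5)
        assert list(kept) == [0, 1, 2, 3]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 9999), st.floats(0.05, 1.0), st.integers(1, 60))
    def test_matches_sort_based_brute_force(self, seed, frac, n):
        d = np.random.default_rng(seed).uniform(0, 1, n).round(2)  # force ties
        kept = trim_correspondences(d, frac)
        k = max(1, int(np.floor(frac * n)))
        order = sorted(range(n), key=lambda i: (d[i], i))
        assert sorted(kept) == sorted(order[:k])


class TestICP:
    def test_recovers_known_displacement(self, tooth):
        truth = RigidTransform(
            Rotation.from_euler("x", 5, degrees=True).as_matrix(), [0.5, -0.2, 0.3]
        )
        target = tooth.mesh.transformed(truth)
        region = RegionMask("crown", tooth.masks["crown"])
        res = icp_register(tooth.mesh, region, target, ICPSettings())
        assert res.rms_residual < 1e-6
        p = tooth.mesh.vertices[region.indices]
        assert np.sqrt(np.mean((res.transform.apply(p) - truth.apply(p)) ** 2)) < 1e-6

    def test_already_aligned_stays_put(self, tooth):
        region = RegionMask("crown", tooth.masks["crown"])
        res = icp_register(tooth.mesh, region, tooth.mesh, ICPSettings())
        assert res.rms_residual < 1e-9
        assert res.iterations_run <= 3
        assert np.allclose(res.transform.matrix(), np.eye(4), atol=1e-9)

    def test_point_to_point_rms_monotone(self, tooth):
        # strict non-increase of the trimmed RMS across iterations
        truth = random_rigid(4, max_deg=8)
        target = tooth.mesh.transformed(truth)
        region = RegionMask("crown", tooth.masks["crown"])
        res = icp_register(
            tooth.mesh, region, target,
            ICPSettings(matching="point_to_point", overlap_fraction=0.6,
                        exclude_overhangs=False, convergence_tol=0.0,
                        max_iterations=25),
        )
        hist = np.asarray(res.rms_history)
        assert (np.diff(hist) <= 1e-12).all()

    def test_retained_count_matches_overlap(self, tooth):
        region = RegionMask("crown", tooth.masks["crown"])
        res = icp_register(
            tooth.mesh, region, tooth.mesh, ICPSettings(overlap_fraction=0.2)
        )
        assert res.retained_count == int(np.floor(0.2 * len(region.indices)))


class TestStaged:
    def landmarks_for(self, tooth, transform):
        lm = np.array([tooth.landmarks[k] for k in ("tip", "gingival_mid_buccal", "mesial", "distal")])
        return lm, transform.apply(lm)

    def test_three_stages_below_half_overlap(self, tooth):
        truth = random_rigid(5)
        target = tooth.mesh.transformed(truth)
        region = RegionMask("crown", tooth.masks["crown"])
        res = staged_register(
            tooth.mesh, region, target, ICPSettings(overlap_fraction=0.2),
            self.landmarks_for(tooth, truth),
        )
        assert res.stages == ["coarse", "approximation_100", "final_0.2"]

    def test_two_stages_at_full_overlap(self, tooth):
        truth = random_rigid(6)
        target = tooth.mesh.transformed(truth)
        region = RegionMask("crown", tooth.masks["crown"])
        res = staged_register(
            tooth.mesh, region, target, ICPSettings(overlap_fraction=1.0),
            self.landmarks_for(tooth, truth),
        )
        assert res.stages == ["coarse", "final_1"]

    def test_deterministic_given_seed(self, tooth):
        truth = random_rigid(7)
        target = tooth.mesh.transformed(truth)
        region = RegionMask("crown", tooth.masks["crown"])
        lm = self.landmarks_for(tooth, truth)
        a = staged_register(tooth.mesh, region, target,
                            ICPSettings(overlap_fraction=0.4), lm, seed=3)
        b = staged_register(tooth.mesh, region, target,
                            ICPSettings(overlap_fraction=0.4), lm, seed=3)
        assert np.array_equal(a.transform.matrix(), b.transform.matrix())

    @pytest.mark.parametrize("seed", range(10))
    def test_transform_recovery_property(self, tooth, seed):
        # rotation <= 20 deg, translation <= 5 mm, full overlap: the staged
        # pipeline must recover the displacement to 1e-5 mm RMS
        truth = random_rigid(100 + seed, max_deg=20, max_t=5)
        target = tooth.mesh.transformed(truth)
        region = RegionMask("crown", tooth.masks["crown"])
        res = staged_register(
            tooth.mesh, region, target, ICPSettings(overlap_fraction=1.0),
            self.landmarks_for(tooth, truth),
        )
        p = tooth.mesh.vertices[region.indices]
        rms = np.sqrt(np.mean(np.sum((res.transform.apply(p) - truth.apply(p)) ** 2, axis=1)))
        assert rms < 1e-5


class TestOverlapSearch:
    def test_identical_meshes_prefer_full_overlap(self, tooth):
        region = RegionMask("crown", tooth.masks["crown"])
        lm = np.array([tooth.landmarks[k] for k in ("tip", "gingival_mid_buccal", "mesial", "distal")])
        best, scores = optimize_overlap_fraction(
            tooth.mesh, region, tooth.mesh, region, (lm, lm),
            grid=np.array([0.25, 0.5, 1.0]),
        )
        assert best == 1.0

    def test_singleton_grid_returned(self, tooth):
        region = RegionMask("crown", tooth.masks["crown"])
        lm = np.array([tooth.landmarks[k] for k in ("tip", "gingival_mid_buccal", "mesial", "distal")])
        best, _ = optimize_overlap_fraction(
            tooth.mesh, region, tooth.mesh, region, (lm, lm), grid=np.array([0.2])
        )
        assert best == 0.2

    def test_empty_grid_rejected(self, tooth):
        region = RegionMask("crown", tooth.masks["crown"])
        lm = np.zeros((4, 3))
        with pytest.raises(InvalidInputError):
            optimize_overlap_fraction(
                tooth.mesh, region, tooth.mesh, region, (lm, lm), grid=np.array([])
            )

    def test_partially_changed_surface_caps_fraction(self, tooth):
        # raise ~30% of the crown (the occlusal third) by 1 mm: the best
        # overlap must not exceed the truly unchanged share plus one step
        mesh = tooth.mesh.copy()
        crown = tooth.masks["crown"]
        z = mesh.vertices[:, 2]
        lifted = crown[z[crown] > np.quantile(z[crown], 0.7)]
        mesh2 = mesh.copy()
        mesh2.vertices[lifted] += [0, 0, 1.0]
        region = RegionMask("crown", crown)
        intact = RegionMask("intact", np.setdiff1d(crown, lifted))
        lm_idx = intact.indices[[0, len(intact.indices) // 3, 2 * len(intact.indices) // 3, -1]]
        lm = mesh.vertices[lm_idx]
        best, scores = optimize_overlap_fraction(
            mesh, region, mesh2, intact, (lm, lm),
            grid=np.round(np.arange(0.1, 1.01, 0.1), 2),
        )
        assert best <= 0.75
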