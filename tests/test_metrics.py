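"""Surface-distance and volumetric-overlap metrics against analytic cases
and the brute-force point-to-triangle oracle."""

import numpy as np
import pytest
import trimesh

from crestseg import metrics, roi
from crestseg.meshes import CuttingPlane, sample_surface


def square_sheet(z: float, size: float = 100.0, n: int = 10) -> trimesh.Trimesh:
    """A flat square sheet at height z, triangulated on an n x n grid."""
    xs = np.linspace(0, size, n + 1)
    xv, yv = np.meshgrid(xs, xs, indexing="ij")
    verts = np.stack([xv.ravel(), yv.ravel(), np.full(xv.size, z)], axis=1)
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = a + 1
            c = a + (n + 1)
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    return trimesh.Trimesh(vertices=verts, faces=faces)


def cube(side=10.0, offset=(0, 0, 0)) -> trimesh.Trimesh:
    t = trimesh.transformations.translation_matrix(np.asarray(offset, float))
    return trimesh.creation.box(extents=[side] * 3, transform=t)


class TestPointTriangleDistance:
    def test_against_vertex_edge_face_cases(self):
        tri = np.array([[[0, 0, 0], [4, 0, 0], [0, 4, 0]]], dtype=float)
        cases = [
            ((1, 1, 5), 5.0),          # face region
            ((-3, -4, 0), 5.0),        # vertex A region
            ((2, -3, 4), 5.0),         # edge AB region
            ((5, 5, 0), np.sqrt(2) * 3 / np.sqrt(2) ** 2 * 1),  # beyond hyp.
        ]
        for p, expected in cases[:3]:
            d = metrics._pair_distances(np.array([p], dtype=float), tri)
            assert d[0] == pytest.approx(expected, abs=1e-12)

    def test_accelerated_equals_bruteforce(self, icosphere):
        rng = np.random.default_rng(0)
        points = rng.uniform(-15, 15, (400, 3))
        fast = metrics.directed_distances(points, icosphere)
        slow = metrics.directed_distances_bruteforce(points, icosphere)
        np.testing.assert_allclose(fast, slow, atol=1e-10)


class TestMeshDice:
    def test_identical_cubes(self):
        assert metrics.mesh_dice(cube(), cube(), pitch=0.5) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_cubes(self):
        assert metrics.mesh_dice(cube(), cube(offset=(30, 0, 0)), pitch=0.5) == 0.0

    def test_half_shifted_cube(self):
        # overlap slab 5x10x10 -> DSC = 2*500/(1000+1000) = 0.5
        d = metrics.mesh_dice(cube(), cube(offset=(5, 0, 0)), pitch=0.5)
        assert d == pytest.approx(0.5, rel=0.02)

    def test_one_empty_is_zero(self):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        assert metrics.mesh_dice(cube(), empty, pitch=0.5) == 0.0

    def test_both_empty_undefined(self):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            metrics.mesh_dice(empty, empty)

    def test_symmetry(self, icosphere):
        a = cube(offset=(2, 1, 0))
        assert metrics.mesh_dice(a, icosphere, pitch=1.0) == pytest.approx(
            metrics.mesh_dice(icosphere, a, pitch=1.0), abs=1e-12)

    def test_pitch_convergence(self):
        """Dice converges as the shared voxel grid is refined."""
        a, b = cube(), cube(offset=(3, 0, 0))
        exact = 0.7  # overlap 7*10*10 over volumes 1000 each
        errs = [abs(metrics.mesh_dice(a, b, pitch=p) - exact) for p in (2.0, 1.0, 0.5)]
        assert errs[2] <= errs[0] + 1e-9
        assert errs[2] < 0.01


class TestSurfaceDistances:
    def test_identical_meshes_zero(self, icosphere):
        assert metrics.asd_symmetric(icosphere, icosphere, 2000, seed=0) \
            == pytest.approx(0.0, abs=1e-9)
        assert metrics.hd95_symmetric(icosphere, icosphere, 2000, seed=0) \
            == pytest.approx(0.0, abs=1e-9)

    def test_parallel_sheets_constant_distance(self):
        a, b = square_sheet(0.0), square_sheet(2.0)
        assert metrics.asd_symmetric(a, b, 20000, seed=1) == pytest.approx(2.0, rel=0.01)
        assert metrics.hd95_symmetric(a, b, 20000, seed=1) == pytest.approx(2.0, rel=0.01)

    def test_concentric_spheres_radial_distance(self):
        a = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        b = trimesh.creation.icosphere(subdivisions=3, radius=12.0)
        assert metrics.asd_symmetric(a, b, 20000, seed=2) == pytest.approx(2.0, rel=0.02)

    def test_hd95_robust_to_small_bump_hd100_not(self):
        """A 4 mm spike on <1% of the surface moves the max, not the 95th pct."""
        a = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        b = trimesh.creation.icosphere(subdivisions=3, radius=11.0)
        bumped = b.copy()
        verts = bumped.vertices.copy()
        direction = verts / np.linalg.norm(verts, axis=1, keepdims=True)
        polar = direction[:, 2] > 0.985  # small cap, <1% of the sphere
        verts[polar] += direction[polar] * 4.0
        bumped.vertices = verts
        hd95 = metrics.hd95_symmetric(a, bumped, 20000, seed=3)
        pa, _ = sample_surface(a, 20000, seed=3)
        pb, _ = sample_surface(bumped, 20000, seed=4)
        hd100 = max(metrics.directed_distances(pa, bumped).max(),
                    metrics.directed_distances(pb, a).max())
        assert hd95 == pytest.approx(1.0, rel=0.15)
        assert hd100 >= 3.0
        assert hd95 <= hd100

    def test_agreement_with_bruteforce_oracle(self):
        """Accelerated ASD/HD95 within 1% of the O(N*M) oracle."""
        pairs = [
            (square_sheet(0.0, n=8), square_sheet(2.0, n=8)),
            (trimesh.creation.icosphere(2, radius=10.0),
             trimesh.creation.icosphere(2, radius=12.0)),
        ]
        for a, b in pairs:
            pa, _ = sample_surface(a, 4000, seed=5)
            pb, _ = sample_surface(b, 6, seed=6)
            fast = metrics.directed_distances(pa, b)
            slow = metrics.directed_distances_bruteforce(pa, b)
            np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-12)

    def test_symmetry_at_fixed_seed(self):
        a = trimesh.creation.icosphere(2, radius=10.0)
        b = cube(8.0, offset=(3, 0, 0))
        # pooled distances swap roles but the pooled set is sampled per mesh;
        # symmetric within sampling tolerance
        d1 = metrics.asd_symmetric(a, b, 20000, seed=7)
        d2 = metrics.asd_symmetric(b, a, 20000, seed=7)
        assert d1 == pytest.approx(d2, rel=0.05)

    def test_hd95_max_variant_bounds_pooled(self):
        a = trimesh.creation.icosphere(2, radius=10.0)
        b = trimesh.creation.icosphere(2, radius=12.0)
        pooled = metrics.hd95_symmetric(a, b, 5000, seed=8, how="pooled")
        mx = metrics.hd95_symmetric(a, b, 5000, seed=8, how="max")
        assert mx >= pooled - 1e-9


class TestPerPointDistances:
    def test_identical_all_zero(self, icosphere):
        _, d = metrics.per_point_distances(icosphere, icosphere, 1000, seed=0)
        np.testing.assert_allclose(d, 0, atol=1e-9)

    def test_sheets_all_offset(self):
        _, d = metrics.per_point_distances(square_sheet(0.0), square_sheet(2.0),
                                           2000, seed=1)
        np.testing.assert_allclose(d, 2.0, atol=1e-9)

    def test_mean_consistent_with_directed_asd_term(self):
        a = trimesh.creation.icosphere(2, radius=10.0)
        b = trimesh.creation.icosphere(2, radius=12.0)
        _, d = metrics.per_point_distances(a, b, 30000, seed=2)
        assert d.mean() == pytest.approx(2.0, rel=0.02)

    def test_ply_export(self, tmp_path, icosphere):
        pts, d = metrics.per_point_distances(icosphere, icosphere, 50, seed=0)
        path = tmp_path / "cloud.ply"
        metrics.export_distance_cloud(pts, d, path)
        text = path.read_text()
        assert "element vertex 50" in text
        assert "property float quality" in text


class TestEvaluateCase:
    def _rois(self):
        left = roi.RoiDefinition(anchor=[-0.3, 0, 0.2],
                                 normal=np.array([-0.6, 0, 0.8]), side="left")
        return [left, roi.mirror_roi(left)]

    def test_self_comparison_perfect(self):
        m = trimesh.creation.icosphere(3, radius=25.0)
        m.apply_scale([1.5, 1.0, 0.8])
        reports = metrics.evaluate_case(m, m, self._rois(), pitch=1.0,
                                        n_points=5000, seed=0)
        assert set(reports) == {"whole", "left_roi", "right_roi"}
        for rep in reports.values():
            assert rep.dsc == pytest.approx(1.0, abs=0.02)
            assert rep.asd_mm == pytest.approx(0.0, abs=1e-9)

    def test_dilated_prediction_asd_about_offset(self):
        truth = trimesh.creation.icosphere(3, radius=20.0)
        pred = trimesh.creation.icosphere(3, radius=21.0)  # 1 mm outward
        reports = metrics.evaluate_case(pred, truth, None, pitch=0.5,
                                        n_points=10000, seed=1)
        assert reports["whole"].asd_mm == pytest.approx(1.0, rel=0.05)

    def test_same_plane_used_for_both_meshes(self):
        """Prediction and truth ROIs are cut by the identical absolute plane."""
        truth = trimesh.creation.icosphere(3, radius=25.0)
        pred = truth.copy()
        pred.apply_translation([4.0, 0, 0])  # prediction offset shifts ITS center
        rd = self._rois()[0]
        plane_from_truth = roi.absolute_plane(truth, rd)
        plane_from_pred = roi.absolute_plane(pred, rd)
        # the two centers differ, so deriving from each mesh would disagree
        assert not np.allclose(plane_from_truth.anchor, plane_from_pred.anchor)
        reports = metrics.evaluate_case(pred, truth, [rd], pitch=1.0,
                                        n_points=3000, seed=2)
        assert reports["left_roi"].dsc is not None
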