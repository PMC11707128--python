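"""Mesh I/O, marching cubes, greedy voxelization, sampling, clipping."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from crestseg import meshes
from conftest import make_ball_field


class TestMeshIO:
    def test_cube_stl_roundtrip_topology(self, unit_cube, tmp_path):
        meshes.write_mesh(unit_cube, tmp_path / "cube.stl")
        back = meshes.read_mesh(tmp_path / "cube.stl")
        assert len(back.faces) == 12
        assert len(back.vertices) == 8

    def test_empty_mesh_write_rejected(self, tmp_path):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        with pytest.raises(meshes.MeshFormatError):
            meshes.write_mesh(empty, tmp_path / "e.stl")

    @pytest.mark.parametrize("ext", ["stl", "ply"])
    def test_icosphere_roundtrip(self, icosphere, tmp_path, ext):
        path = tmp_path / f"s.{ext}"
        meshes.write_mesh(icosphere, path)
        back = meshes.read_mesh(path)
        a = np.sort(np.round(np.asarray(icosphere.vertices), 5), axis=0)
        b = np.sort(np.round(np.asarray(back.vertices), 5), axis=0)
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_malformed_file(self, tmp_path):
        p = tmp_path / "bad.stl"
        p.write_bytes(b"solid nonsense\n garbage\n")
        with pytest.raises(meshes.MeshFormatError):
            meshes.read_mesh(p)


class TestMarchingCubes:
    def test_all_zero_field_empty_mesh(self):
        out = meshes.marching_cubes(np.zeros((8, 8, 8)), 0.5)
        assert len(out.faces) == 0

    def test_ball_surface_area_and_volume(self):
        r = 20.0
        mesh = meshes.marching_cubes(make_ball_field(r, 51), 0.5)
        assert mesh.is_watertight
        assert mesh.area == pytest.approx(4 * np.pi * r ** 2, rel=0.05)
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * r ** 3, rel=0.05)

    def test_vertices_in_mm_coordinates(self):
        field = make_ball_field(5.0, 16)
        mesh = meshes.marching_cubes(field, 0.5, spacing=(2, 2, 2), origin=(10, 20, 30))
        center = mesh.vertices.mean(axis=0)
        np.testing.assert_allclose(center, [10 + 15, 20 + 15, 30 + 15], atol=0.5)

    def test_origin_translation_equivariance(self):
        field = make_ball_field(6.0, 20)
        m0 = meshes.marching_cubes(field, 0.5, origin=(0, 0, 0))
        m1 = meshes.marching_cubes(field, 0.5, origin=(5, -3, 2))
        np.testing.assert_allclose(m1.vertices - [5, -3, 2], m0.vertices, atol=1e-6)


def _box_at(lo, size):
    lo = np.asarray(lo, float)
    size = np.asarray(size, float)
    t = trimesh.transformations.translation_matrix(lo + size / 2)
    return trimesh.creation.box(extents=size, transform=t)


class TestGreedyVoxelize:
    def test_aligned_cube_exact_count(self):
        # cube spans voxels 0..3 exactly on each axis
        cube = _box_at([-0.5, -0.5, -0.5], [4, 4, 4])
        mask = meshes.greedy_voxelize(cube, (8, 8, 8), (1, 1, 1), (0, 0, 0))
        assert mask.voxel_count == 64

    def test_quarter_voxel_shift_grows_one_layer(self):
        cube = _box_at([-0.25, -0.5, -0.5], [4, 4, 4])
        mask = meshes.greedy_voxelize(cube, (8, 8, 8), (1, 1, 1), (0, 0, 0))
        assert mask.voxel_count == 80  # 5 x 4 x 4

    def test_sphere_superset_of_centers(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        sphere.apply_translation([8, 8, 8])
        greedy = meshes.greedy_voxelize(sphere, (16, 16, 16), (1, 1, 1), (0, 0, 0))
        centers = meshes.voxelize_centers(sphere, (16, 16, 16), (1, 1, 1), (0, 0, 0))
        assert np.all(greedy.data >= centers)
        assert greedy.voxel_count > centers.sum()

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_random_blob_superset_property(self, seed):
        """Greedy mask contains the centre-containment mask for random blobs."""
        rng = np.random.default_rng(seed)
        center = rng.uniform(6, 10, 3)
        radii = rng.uniform(2.0, 4.5, 3)
        blob = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        blob.apply_scale(radii)
        blob.apply_translation(center)
        greedy = meshes.greedy_voxelize(blob, (16, 16, 16), (1, 1, 1), (0, 0, 0))
        centers = meshes.voxelize_centers(blob, (16, 16, 16), (1, 1, 1), (0, 0, 0))
        assert np.all(greedy.data >= centers)

    def test_greedy_then_marching_cubes_recovers_cube_volume(self):
        cube = _box_at([4.5, 4.5, 4.5], [10, 10, 10])
        mask = meshes.greedy_voxelize(cube, (20, 20, 20), (1, 1, 1), (0, 0, 0))
        surf = meshes.marching_cubes(mask.data.astype(np.float32), 0.5)
        # one-voxel shell tolerance around the 10^3 cube
        assert 10 ** 3 * 0.75 < surf.volume < 12 ** 3

    def test_empty_mesh_rejected(self):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        with pytest.raises(meshes.VoxelizationError):
            meshes.greedy_voxelize(empty, (4, 4, 4), (1, 1, 1), (0, 0, 0))


class TestSampleSurface:
    def test_points_on_triangle_plane(self):
        tri = trimesh.Trimesh(vertices=[[0, 0, 0], [4, 0, 0], [0, 4, 0]],
                              faces=[[0, 1, 2]])
        pts, w = meshes.sample_surface(tri, 1000, seed=0)
        assert np.all(np.abs(pts[:, 2]) < 1e-9)
        assert w.sum() == pytest.approx(tri.area)

    def test_area_proportional_density(self):
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [3, 0, 0], [0, 2, 0], [10, 0, 0], [11, 0, 0], [10, 1, 0]],
            faces=[[0, 1, 2], [3, 4, 5]],
        )  # areas 3 and 0.5 -> ratio 6:1
        pts, _ = meshes.sample_surface(mesh, 42000, seed=1)
        n_big = (pts[:, 0] < 5).sum()
        ratio = n_big / (len(pts) - n_big)
        assert ratio == pytest.approx(6.0, rel=0.1)

    def test_deterministic_per_seed(self, icosphere):
        p1, _ = meshes.sample_surface(icosphere, 500, seed=7)
        p2, _ = meshes.sample_surface(icosphere, 500, seed=7)
        np.testing.assert_array_equal(p1, p2)

    def test_empty_mesh_error(self):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            meshes.sample_surface(empty, 10, seed=0)


class TestClipByPlane:
    def test_plane_below_mesh_is_noop(self, unit_cube):
        plane = meshes.CuttingPlane([0, 0, -5], [0, 0, 1])
        out = meshes.clip_by_plane(unit_cube, plane)
        assert out.area == pytest.approx(unit_cube.area, rel=1e-9)

    def test_cube_midplane_areas(self, unit_cube):
        plane = meshes.CuttingPlane([0, 0, 0], [0, 0, 1])
        top = meshes.clip_by_plane(unit_cube, plane)
        # kept: 4 half side-faces (4 * 0.5) + top cap (1) = 3
        assert top.area == pytest.approx(3.0, rel=1e-6)

    def test_area_conservation(self, icosphere):
        plane = meshes.CuttingPlane([0, 0, 2.0], [0.3, 0.4, np.sqrt(1 - 0.25)])
        kept = meshes.clip_by_plane(icosphere, plane)
        flipped = meshes.CuttingPlane([0, 0, 2.0], -plane.normal)
        discarded = meshes.clip_by_plane(icosphere, flipped)
        assert kept.area + discarded.area == pytest.approx(icosphere.area, rel=1e-6)

    def test_idempotence(self, icosphere):
        plane = meshes.CuttingPlane([1, 0, 0], [1, 0, 0])
        once = meshes.clip_by_plane(icosphere, plane)
        twice = meshes.clip_by_plane(once, plane)
        assert twice.area == pytest.approx(once.area, rel=1e-9)

    def test_fully_negative_gives_empty(self, unit_cube):
        plane = meshes.CuttingPlane([0, 0, 10], [0, 0, 1])
        out = meshes.clip_by_plane(unit_cube, plane)
        assert len(out.faces) == 0

    def test_translation_equivariance(self, icosphere):
        plane = meshes.CuttingPlane([0, 0, 0], [0, 0, 1])
        moved = icosphere.copy()
        moved.apply_translation([7, -2, 3])
        plane_moved = meshes.CuttingPlane([7, -2, 3], [0, 0, 1])
        a = meshes.clip_by_plane(icosphere, plane)
        b = meshes.clip_by_plane(moved, plane_moved)
        assert b.area == pytest.approx(a.area, rel=1e-9)


class TestGeometricCenter:
    def test_centered_cube(self, unit_cube):
        np.testing.assert_allclose(meshes.geometric_center(unit_cube), 0, atol=1e-12)

    def test_translation_equivariance(self, unit_cube):
        moved = unit_cube.copy()
        moved.apply_translation([3, 4, 5])
        np.testing.assert_allclose(meshes.geometric_center(moved), [3, 4, 5], atol=1e-12)

    def test_l_prism_matches_monte_carlo(self):
        a = _box_at([0, 0, 0], [4, 1, 1])
        b = _box_at([0, 1, 0], [1, 3, 1])
        lshape = trimesh.util.concatenate([a, b])
        center = meshes.geometric_center(lshape)
        pts, _ = meshes.sample_surface(lshape, 400_000, seed=0)
        np.testing.assert_allclose(center, pts.mean(axis=0), atol=2e-2)

    def test_empty_error(self):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            meshes.geometric_center(empty)
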