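"""Triangle-mesh operations: I/O, marching cubes, voxelization, clipping.

Meshes live in patient millimetre coordinates and are carried as
:class:`trimesh.Trimesh` objects. The module provides the two rasterization
paths used throughout the pipeline:

* ``voxelize_centers`` — the classical centre-containment mask (a voxel is
  foreground iff its centre lies inside the closed surface), computed by
  even-odd parity counting along z columns;
* ``greedy_voxelize`` — the training-mask rasterization: every voxel whose
  axis-aligned box has *some extent* inside the mesh (surface or interior) is
  foreground. This is the centre mask united with all voxels whose box
  intersects a surface triangle, so it is always a superset of the centre mask.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .grid import BinaryMask


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or is degenerate."""


class VoxelizationError(ValueError):
    """Raised when a mesh cannot define a consistent inside/outside."""


@dataclasses.dataclass
class CuttingPlane:
    """A plane given by an anchor point and a unit normal."""

    anchor: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=np.float64).reshape(3)
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(self.normal)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("plane normal must be non-zero")
            self.normal = self.normal / norm


# ---------------------------------------------------------------------------
# I/O

def read_mesh(path: str | os.PathLike) -> trimesh.Trimesh:
    """Read an STL (binary/ASCII) or PLY mesh."""
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as exc:
        raise MeshFormatError(f"cannot read mesh {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshFormatError(f"{path}: no triangle data found")
    mesh.merge_vertices()
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | os.PathLike) -> None:
    if len(mesh.faces) == 0:
        raise MeshFormatError("refusing to write an empty mesh")
    mesh.export(str(path))


# ---------------------------------------------------------------------------
# Marching cubes

def marching_cubes(
    field: np.ndarray,
    iso: float,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> trimesh.Trimesh:
    """Extract the iso-surface of a scalar grid as a mesh in mm coordinates.

    Vertex positions follow the grid geometry convention: grid index ``(i,j,k)``
    sits at ``origin + (i,j,k) * spacing``. An iso value outside the field's
    range yields an empty mesh rather than an error.
    """
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 3 or min(field.shape) < 2:
        raise ValueError(f"field must be 3D with >=2 samples per axis, got {field.shape}")
    if not (field.min() < iso < field.max()):
        return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))
    verts, faces, _normals, _values = measure.marching_cubes(
        field, level=iso, spacing=tuple(float(s) for s in spacing)
    )
    verts = verts + np.asarray(origin, dtype=np.float64)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # Orient outward (positive enclosed volume) for downstream volume checks.
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# Voxelization

def _column_crossings(verts_idx: np.ndarray, faces: np.ndarray, nx: int, ny: int):
    """All (column id, z) ray crossings of the surface, columns = ix*ny + iy.

    Vertical rays pass through integer (ix, iy); triangle coordinates receive a
    tiny fixed jitter so rays never hit edges or vertices exactly.
    """
    tri = verts_idx[faces].astype(np.float64)  # (T, 3, 3)
    tri = tri + np.array([3.239e-7, 7.771e-7, 0.0])
    xy = tri[:, :, :2]
    z = tri[:, :, 2]

    lo = np.ceil(xy.min(axis=1)).astype(np.int64)
    hi = np.floor(xy.max(axis=1)).astype(np.int64)
    lo[:, 0] = np.clip(lo[:, 0], 0, nx - 1)
    lo[:, 1] = np.clip(lo[:, 1], 0, ny - 1)
    hi[:, 0] = np.clip(hi[:, 0], -1, nx - 1)
    hi[:, 1] = np.clip(hi[:, 1], -1, ny - 1)
    span = np.maximum(hi - lo + 1, 0)
    counts = span[:, 0] * span[:, 1]
    keep = counts > 0
    if not np.any(keep):
        return np.zeros(0, dtype=np.int64), np.zeros(0)
    tri_ids = np.repeat(np.nonzero(keep)[0], counts[keep])
    # Local candidate enumeration within each triangle's xy bounding box.
    offs = np.concatenate([np.arange(c) for c in counts[keep]])
    sx = span[tri_ids, 1]
    ix = lo[tri_ids, 0] + offs // sx
    iy = lo[tri_ids, 1] + offs % sx

    p = np.stack([ix, iy], axis=1).astype(np.float64)
    a, b, c = xy[tri_ids, 0], xy[tri_ids, 1], xy[tri_ids, 2]
    d = (b[:, 1] - c[:, 1]) * (a[:, 0] - c[:, 0]) + (c[:, 0] - b[:, 0]) * (a[:, 1] - c[:, 1])
    ok = np.abs(d) > 1e-30
    w0 = np.where(ok, ((b[:, 1] - c[:, 1]) * (p[:, 0] - c[:, 0])
                       + (c[:, 0] - b[:, 0]) * (p[:, 1] - c[:, 1])) / np.where(ok, d, 1.0), -1)
    w1 = np.where(ok, ((c[:, 1] - a[:, 1]) * (p[:, 0] - c[:, 0])
                       + (a[:, 0] - c[:, 0]) * (p[:, 1] - c[:, 1])) / np.where(ok, d, 1.0), -1)
    w2 = 1.0 - w0 - w1
    inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0) & ok
    if not np.any(inside):
        return np.zeros(0, dtype=np.int64), np.zeros(0)
    zt = z[tri_ids]
    z_cross = (w0 * zt[:, 0] + w1 * zt[:, 1] + w2 * zt[:, 2])[inside]
    col = (ix * ny + iy)[inside]
    return col, z_cross


def voxelize_centers(
    mesh: trimesh.Trimesh,
    shape: tuple[int, int, int],
    spacing,
    origin,
) -> np.ndarray:
    """Centre-containment rasterization of a closed surface, as a bool grid."""
    nx, ny, nz = (int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=np.float64)
    origin = np.asarray(origin, dtype=np.float64)
    out = np.zeros((nx, ny, nz), dtype=bool)
    if len(mesh.faces) == 0:
        return out
    verts_idx = (mesh.vertices - origin) / spacing
    col, z_cross = _column_crossings(verts_idx, mesh.faces, nx, ny)
    if col.size == 0:
        return out
    order = np.lexsort((z_cross, col))
    col, z_cross = col[order], z_cross[order]
    # Pair consecutive crossings within each column: (entry, exit) intervals.
    seg_start = np.r_[0, np.nonzero(np.diff(col))[0] + 1]
    seg_len = np.r_[np.diff(seg_start), col.size - seg_start[-1]]
    local = np.arange(col.size) - np.repeat(seg_start, seg_len)
    local_n = np.repeat(seg_len, seg_len)
    is_entry = (local % 2 == 0) & (local + 1 < local_n)
    z_in = z_cross[is_entry]
    z_out = z_cross[np.nonzero(is_entry)[0] + 1]
    cols = col[is_entry]
    k0 = np.clip(np.floor(z_in).astype(np.int64) + 1, 0, nz)
    k1 = np.clip(np.floor(z_out).astype(np.int64), -1, nz - 1)
    valid = k0 <= k1
    if not np.any(valid):
        return out
    diff = np.zeros((nx * ny, nz + 1), dtype=np.int32)
    np.add.at(diff, (cols[valid], k0[valid]), 1)
    np.add.at(diff, (cols[valid], k1[valid] + 1), -1)
    inside = np.cumsum(diff[:, :-1], axis=1) > 0
    return inside.reshape(nx, ny, nz)


def _tri_box_overlap(tri: np.ndarray) -> np.ndarray:
    """Separating-axis test of triangles vs unit cubes centred at the origin.

    ``tri``: (P, 3, 3) triangle vertices relative to each box centre, in units
    where the box half-extent is 0.5 per axis. Returns a bool per pair. The
    overlap is *strict*: a triangle merely touching a box face or corner has
    zero extent inside and does not count — this is what makes the aligned
    greedy-cube case exact.
    """
    h = 0.5
    eps = 1e-9
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    ok = np.ones(len(tri), dtype=bool)

    # Box face axes (AABB overlap).
    mn = tri.min(axis=1)
    mx = tri.max(axis=1)
    ok &= np.all((mn < h - eps) & (mx > -h + eps), axis=1)

    # Triangle plane vs box.
    e0, e1 = v1 - v0, v2 - v1
    n = np.cross(e0, e1)
    r = h * np.abs(n).sum(axis=1)
    s = np.einsum("ij,ij->i", n, v0)
    ok &= np.abs(s) < r - eps

    # 9 cross-product axes a = e_i x f_j.
    edges = (e0, e1, v0 - v2)
    for e in edges:
        for axis in range(3):
            u = np.zeros((len(tri), 3))
            u[:, axis] = 1.0
            a = np.cross(u, e)
            p0 = np.einsum("ij,ij->i", a, v0)
            p1 = np.einsum("ij,ij->i", a, v1)
            p2 = np.einsum("ij,ij->i", a, v2)
            pmin = np.minimum(np.minimum(p0, p1), p2)
            pmax = np.maximum(np.maximum(p0, p1), p2)
            rad = h * np.abs(a).sum(axis=1)
            degenerate = rad < 1e-12  # edge parallel to box axis: no information
            ok &= degenerate | ((pmin < rad - eps) & (pmax > -rad + eps))
    return ok


def _surface_voxels(verts_idx: np.ndarray, faces: np.ndarray, shape) -> np.ndarray:
    """All voxels whose box intersects any surface triangle (index coords)."""
    nx, ny, nz = shape
    out = np.zeros((nx, ny, nz), dtype=bool)
    tri_all = verts_idx[faces]  # (T, 3, 3)
    lo = np.ceil(tri_all.min(axis=1) - 0.5).astype(np.int64)
    hi = np.floor(tri_all.max(axis=1) + 0.5).astype(np.int64)
    lims = np.array([nx, ny, nz]) - 1
    lo = np.clip(lo, 0, lims)
    hi = np.minimum(hi, lims)
    span = np.maximum(hi - lo + 1, 0)
    counts = span.prod(axis=1)
    keep = counts > 0
    if not np.any(keep):
        return out
    tri_ids = np.repeat(np.nonzero(keep)[0], counts[keep])
    offs = np.concatenate([np.arange(c) for c in counts[keep]])
    sy, sz = span[tri_ids, 1], span[tri_ids, 2]
    iz = lo[tri_ids, 2] + offs % sz
    iy = lo[tri_ids, 1] + (offs // sz) % sy
    ix = lo[tri_ids, 0] + offs // (sz * sy)
    centers = np.stack([ix, iy, iz], axis=1).astype(np.float64)
    rel = tri_all[tri_ids] - centers[:, None, :]
    hit = _tri_box_overlap(rel)
    out[ix[hit], iy[hit], iz[hit]] = True
    return out


def greedy_voxelize(
    mesh: trimesh.Trimesh,
    shape: tuple[int, int, int],
    spacing,
    origin,
) -> BinaryMask:
    """Greedy mesh rasterization for training-mask generation.

    A voxel is set iff its axis-aligned box ``centre +/- spacing/2`` intersects
    the mesh interior or surface, so the result always contains the full
    triangulated surface and is a superset of the centre-containment mask.
    """
    if len(mesh.faces) == 0:
        raise VoxelizationError("cannot voxelize an empty mesh")
    if not mesh.is_winding_consistent:
        raise VoxelizationError("mesh winding is inconsistent; inside/outside undefined")
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=np.float64)
    origin = np.asarray(origin, dtype=np.float64)
    verts_idx = (mesh.vertices - origin) / spacing
    inside = voxelize_centers(mesh, shape, spacing, origin)
    surface = _surface_voxels(verts_idx, mesh.faces, shape)
    return BinaryMask(data=inside | surface, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# Surface sampling, clipping, centroids

def sample_surface(mesh: trimesh.Trimesh, n_points: int, seed: int):
    """Area-weighted uniform surface samples.

    Returns ``(points, weights)`` where each point carries the same area weight
    ``total_area / n_points``; deterministic for a given seed.
    """
    if len(mesh.faces) == 0:
        raise ValueError("cannot sample an empty mesh")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    areas = mesh.area_faces
    total = areas.sum()
    face_idx = rng.choice(len(areas), size=n_points, p=areas / total)
    r1, r2 = rng.random((2, n_points))
    su = np.sqrt(r1)
    bary = np.stack([1.0 - su, su * (1.0 - r2), su * r2], axis=1)
    tri = mesh.vertices[mesh.faces[face_idx]]
    points = np.einsum("pi,pij->pj", bary, tri)
    weights = np.full(n_points, total / n_points)
    return points, weights


def clip_by_plane(mesh: trimesh.Trimesh, plane: CuttingPlane) -> trimesh.Trimesh:
    """Keep the sub-mesh on the positive side of the plane.

    Crossing triangles are split at the intersection; all disconnected
    fragments on the kept side are retained.
    """
    if len(mesh.faces) == 0:
        return mesh.copy()
    clipped = mesh.slice_plane(
        plane_origin=plane.anchor, plane_normal=plane.normal, cap=False
    )
    if clipped is None or len(clipped.faces) == 0:
        return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))
    return clipped


def geometric_center(mesh: trimesh.Trimesh, method: str = "surface") -> np.ndarray:
    """Geometric centre of a bone mesh.

    ``surface`` (default) is the area-weighted surface centroid, defined for
    any mesh including the non-watertight outputs of post-processing;
    ``volume`` uses the enclosed-volume centroid and requires watertightness.
    """
    if len(mesh.faces) == 0:
        raise ValueError("geometric center of an empty mesh is undefined")
    if method == "surface":
        return np.average(mesh.triangles_center, axis=0, weights=mesh.area_faces)
    if method == "volume":
        if not mesh.is_watertight:
            raise ValueError("volume centroid requires a watertight mesh")
        return np.asarray(mesh.center_mass)
    raise ValueError(f"unknown method {method!r}")
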