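"""Procedural pelvis phantoms: paired CT volumes and ground-truth meshes.

Each phantom emulates the geometry the segmentation pipeline must handle: two
bilateral thin-walled, curved "iliac wing" shells (spherical-shell caps with
per-axis radii, opening caudally) plus a central sacrum-like block, embedded
in a soft-tissue-intensity background. Volume shapes, voxel spacings, wing
parameters and pose vary between cases, mimicking the heterogeneity of
clinical CT acquisitions (in-plane resolution and slice counts vary from scan
to scan).

The bone is defined by an analytic implicit field; the ground-truth mesh is
extracted from a 2x supersampled sampling of that field, and the CT intensity
grid is rasterized *from the mesh* by centre containment, so the mesh and the
voxel data are mutually consistent by construction. Intensities are drawn per
voxel: tissue ~ N(40, 15) HU, bone ~ N(700, 100) HU, plus N(0, 20) HU
acquisition noise — a contrast several pooled standard deviations wide, so
the task is learnable at desk scale.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage

from . import grid, meshes


@dataclasses.dataclass
class PhantomSpec:
    """Parameter ranges for the phantom cohort; defaults are the study conditions."""

    shape_range: tuple = ((64, 80), (64, 80), (64, 88))  # voxels per axis
    spacing_range: tuple = ((1.4, 2.0),) * 3             # mm per voxel
    bone_hu: tuple = (700.0, 100.0)                      # mean, std
    tissue_hu: tuple = (40.0, 15.0)
    noise_sigma: float = 20.0
    wing_radius_rel: tuple = ((0.30, 0.40), (0.42, 0.55), (0.45, 0.60))  # of half-FOV
    wing_thickness: tuple = (0.10, 0.16)    # relative shell thickness
    wing_cut: tuple = (-0.35, -0.15)        # caudal cap cut in shell coords
    sacrum_half_rel: tuple = ((0.10, 0.16), (0.16, 0.24), (0.22, 0.32))
    pose_max_deg: float = 8.0
    asymmetry_jitter: float = 0.02
    seed: int = 0

    def separation_sigmas(self) -> float:
        """Bone/tissue intensity separation in pooled standard deviations."""
        pooled = np.sqrt(self.bone_hu[1] ** 2 + self.tissue_hu[1] ** 2
                         + 2 * self.noise_sigma ** 2)
        return (self.bone_hu[0] - self.tissue_hu[0]) / pooled


@dataclasses.dataclass
class PhantomCase:
    case_id: str
    case_seed: int
    volume: grid.ImageVolume
    mesh: trimesh.Trimesh
    bone_mask: grid.BinaryMask   # centre-containment rasterization of the mesh


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _sample_params(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    shape = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in spec.shape_range)
    spacing = np.array([rng.uniform(lo, hi) for lo, hi in spec.spacing_range])
    half_fov = np.array(shape) * spacing / 2.0
    radii = np.array([rng.uniform(lo, hi) for lo, hi in spec.wing_radius_rel]) * half_fov
    jit = 1.0 + spec.asymmetry_jitter * rng.standard_normal(3)
    thickness = rng.uniform(*spec.wing_thickness)
    cut = rng.uniform(*spec.wing_cut)
    sacrum_half = np.array([rng.uniform(lo, hi) for lo, hi in spec.sacrum_half_rel]) * half_fov
    angles = rng.uniform(-spec.pose_max_deg, spec.pose_max_deg, 3) \
        if spec.pose_max_deg > 0 else np.zeros(3)
    wing_cx = 0.45 * half_fov[0]
    return dict(shape=shape, spacing=spacing, half_fov=half_fov,
                radii_left=radii, radii_right=radii * jit,
                thickness=thickness, cut=cut,
                sacrum_half=sacrum_half, angles=angles, wing_cx=wing_cx)


def _implicit_field(points: np.ndarray, params: dict) -> np.ndarray:
    """Signed inside-ness field (> 0 inside bone) at mm points about the centre."""
    rot = _rotation_matrix(params["angles"])
    p = points @ rot  # apply inverse rotation (R^T) to sample rotated geometry

    def wing(sign: float, radii: np.ndarray) -> np.ndarray:
        c = np.array([sign * params["wing_cx"], 0.0, 0.0])
        q = (p - c) / radii
        r = np.linalg.norm(q, axis=-1)
        shell = params["thickness"] - np.abs(r - 1.0)
        cap = q[..., 2] - params["cut"]
        return np.minimum(shell, cap)

    def sacrum() -> np.ndarray:
        c = np.array([0.0, 0.0, -0.15 * params["half_fov"][2]])
        q = np.abs(p - c) / params["sacrum_half"]
        return 1.0 - np.maximum(np.maximum(q[..., 0], q[..., 1]), q[..., 2])

    return np.maximum(np.maximum(wing(-1.0, params["radii_left"]),
                                 wing(+1.0, params["radii_right"])),
                      sacrum())


def _extract_mesh(params: dict, supersample: int = 2) -> trimesh.Trimesh:
    shape = np.array(params["shape"]) * supersample
    spacing = params["spacing"] / supersample
    # Grid centred on the volume centre; origin in centred mm coordinates.
    origin = -(shape - 1) * spacing / 2.0
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    field = _implicit_field(pts, params).astype(np.float32)
    return meshes.marching_cubes(field, 0.0, spacing, origin)


def generate_phantom(spec: PhantomSpec, case_seed: int,
                     max_retries: int = 5) -> PhantomCase:
    """Generate one phantom; deterministic per ``(spec.seed, case_seed)``."""
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, case_seed, attempt]))
        params = _sample_params(spec, rng)
        mesh = _extract_mesh(params)
        if len(mesh.faces) == 0 or not mesh.is_watertight:
            continue
        shape = params["shape"]
        spacing = params["spacing"]
        origin = -(np.array(shape) - 1) * spacing / 2.0
        bone = meshes.voxelize_centers(mesh, shape, spacing, origin)
        frac = bone.mean()
        if not 0.005 <= frac <= 0.15:
            continue
        n_vox = int(np.prod(shape))
        tissue = rng.normal(spec.tissue_hu[0], spec.tissue_hu[1], n_vox)
        bone_i = rng.normal(spec.bone_hu[0], spec.bone_hu[1], n_vox)
        noise = rng.normal(0.0, spec.noise_sigma, n_vox)
        data = np.where(bone.ravel(), bone_i, tissue) + noise
        volume = grid.ImageVolume(
            data=data.reshape(shape).astype(np.float32),
            spacing=spacing, origin=origin,
        )
        return PhantomCase(
            case_id=f"case_{case_seed:06d}",
            case_seed=int(case_seed),
            volume=volume,
            mesh=mesh,
            bone_mask=grid.BinaryMask(data=bone, spacing=spacing, origin=origin),
        )
    raise RuntimeError(
        f"could not generate a valid phantom for case_seed={case_seed} "
        f"after {max_retries} attempts"
    )


def generate_cohort(spec: PhantomSpec, n: int, seed: int = 0,
                    out_dir=None) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate ``n`` phantoms with distinct case seeds plus a manifest.

    The manifest (case id, case seed, realized shape and spacing) together
    with the spec fully determines the cohort, so it can be regenerated
    byte-identically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    case_seeds = []
    while len(case_seeds) < n:
        s = int(rng.integers(0, 2 ** 31 - 1))
        if s not in case_seeds:
            case_seeds.append(s)
    cases = [generate_phantom(spec, s) for s in case_seeds]
    manifest = pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "case_seed": [c.case_seed for c in cases],
            "shape_x": [c.volume.shape[0] for c in cases],
            "shape_y": [c.volume.shape[1] for c in cases],
            "shape_z": [c.volume.shape[2] for c in cases],
            "spacing_x": [c.volume.spacing[0] for c in cases],
            "spacing_y": [c.volume.spacing[1] for c in cases],
            "spacing_z": [c.volume.spacing[2] for c in cases],
        }
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for c in cases:
            grid.write_volume(c.volume, out_dir / f"{c.case_id}_ct.nii.gz")
            meshes.write_mesh(c.mesh, out_dir / f"{c.case_id}_truth.stl")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return cases, manifest


# ---------------------------------------------------------------------------
# Corruption modes (robustness fixtures; never part of default cohorts)

def corrupt_case(case: PhantomCase, mode: str, seed: int = 0,
                 angle_deg: float = 15.0, crop_fraction: float = 0.25) -> PhantomCase:
    """Emulate the dataset defects that motivated manual exclusion.

    ``implant``: a bright metal-intensity cylinder near the bone;
    ``tilt``: rigid rotation of volume and mesh (patient tilted on the bench);
    ``crop``: truncation of the caudal slices.
    """
    vol, mesh = case.volume, case.mesh
    if mode == "implant":
        rng = np.random.default_rng(seed)
        lo, hi = mesh.bounds
        cx = rng.uniform(lo[0], hi[0])
        cy = rng.uniform(lo[1], hi[1])
        xs = vol.origin[0] + np.arange(vol.shape[0]) * vol.spacing[0]
        ys = vol.origin[1] + np.arange(vol.shape[1]) * vol.spacing[1]
        dist2 = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
        cyl = dist2 <= 4.0 ** 2  # 4 mm radius, full z extent
        data = vol.data.copy()
        data[cyl, :] = 3000.0
        new_vol = vol.copy_with(data=data)
        return dataclasses.replace(case, volume=new_vol)
    if mode == "tilt":
        # tilt about the y (anterior-posterior) axis so the lateral wing
        # axis visibly rotates
        rot = _rotation_matrix(np.array([0.0, angle_deg, 0.0]))
        center_idx = (np.array(vol.shape) - 1) / 2.0
        # output(x) = input(R^T (x - c) + c): content rotated by R about centre.
        scale = np.diag(vol.spacing)
        m = np.linalg.inv(scale) @ rot.T @ scale
        offset = center_idx - m @ center_idx
        data = ndimage.affine_transform(
            vol.data, m, offset=offset, order=1,
            mode="constant", cval=float(vol.data.min()),
        )
        center_mm = vol.origin + center_idx * vol.spacing
        new_mesh = mesh.copy()
        new_mesh.vertices = (mesh.vertices - center_mm) @ rot.T + center_mm
        return dataclasses.replace(case, volume=vol.copy_with(data=data), mesh=new_mesh)
    if mode == "crop":
        nz = vol.shape[2]
        k0 = max(1, int(np.floor(nz * crop_fraction)))
        new_vol = grid.crop_to_box(vol, ((0, vol.shape[0]), (0, vol.shape[1]), (k0, nz)))
        return dataclasses.replace(case, volume=new_vol)
    raise ValueError(f"unknown corruption mode {mode!r}")
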