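"""Volume data model, I/O and resampling.

CT volumes are carried as axis-aligned scalar grids in Hounsfield units with
per-axis spacing in millimetres. The internal axis order is ``(x, y, z)`` with
``x, y`` the in-plane axes, so the volume shapes quoted throughout the package
(e.g. a stage resolution of ``160 x 160 x 224``) read width x height x depth.

The physical position of voxel index ``(i, j, k)`` is
``origin + (i, j, k) * spacing`` (componentwise); each voxel occupies the
axis-aligned box ``centre +/- spacing / 2``.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised when a volume file cannot be parsed."""


class MetadataError(ValueError):
    """Raised when geometry metadata (spacing/origin) is missing or invalid."""


def _as_vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64).reshape(-1)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    return arr


@dataclasses.dataclass
class ImageVolume:
    """A scalar intensity grid with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"data must be a 3D grid, got shape {self.data.shape}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if not np.all(self.spacing > 0):
            raise MetadataError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to mm coordinates."""
        return self.origin + np.asarray(indices, dtype=np.float64) * self.spacing

    def physical_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer bounding box of the grid (voxel faces, not centres), mm."""
        lo = self.origin - self.spacing / 2
        hi = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        return lo, hi

    def copy_with(self, **kwargs) -> "ImageVolume":
        fields = dict(data=self.data, spacing=self.spacing, origin=self.origin)
        fields.update(kwargs)
        return type(self)(**fields)


@dataclasses.dataclass
class BinaryMask(ImageVolume):
    """A boolean occupancy grid sharing :class:`ImageVolume` geometry."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            uniq = np.unique(self.data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be strictly binary")
            self.data = self.data.astype(bool)
        super().__post_init__()

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# I/O

def _read_nifti(path: Path) -> ImageVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise MetadataError(f"{path}: non-positive voxel spacing {zooms}")
    origin = np.asarray(img.affine[:3, 3], dtype=np.float64)
    return ImageVolume(data=data, spacing=np.array(zooms, dtype=np.float64), origin=origin)


def _read_dicom_series(path: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM slices in {path}")
    try:
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        z_positions = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
        px_spacing = [float(v) for v in slices[0].PixelSpacing]
    except AttributeError as exc:
        raise MetadataError(f"{path}: missing spacing/position metadata: {exc}") from exc
    if len(slices) > 1:
        gaps = np.diff(z_positions)
        if np.ptp(gaps) > 1e-3:
            raise MetadataError(f"{path}: non-uniform slice spacing {gaps}")
        dz = float(gaps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # DICOM slices are stored (row, col) = (y, x); transpose to (x, y).
    data = np.stack([p.T for p in planes], axis=-1)
    origin = np.array(
        [float(slices[0].ImagePositionPatient[0]),
         float(slices[0].ImagePositionPatient[1]),
         z_positions[0]],
        dtype=np.float64,
    )
    spacing = np.array([px_spacing[1], px_spacing[0], dz], dtype=np.float64)
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    HU values are returned untouched (DICOM rescale slope/intercept applied).
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return _read_nifti(path)


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume (or mask, as uint8 {0,1}) to NIfTI."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(data=vol.data > 0.5, spacing=vol.spacing, origin=vol.origin)


# ---------------------------------------------------------------------------
# Intensity normalisation

#: Default HU window: the full 12-bit CT range. Keeps cortical-bone contrast
#: while mapping air to 0 and the brightest calcifications/implant metal to 1.
DEFAULT_HU_WINDOW = (-1024.0, 3071.0)


def normalize_intensities(
    volume: ImageVolume, window: tuple[float, float] = DEFAULT_HU_WINDOW
) -> ImageVolume:
    """Clip to ``[lo, hi]`` HU and map affinely to ``[0, 1]``."""
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError(f"degenerate intensity window ({lo}, {hi})")
    data = np.clip(volume.data, lo, hi)
    data = (data - lo) / (hi - lo)
    return volume.copy_with(data=data.astype(np.float32))


# ---------------------------------------------------------------------------
# Resampling and cropping

def resample_to_shape(
    volume: ImageVolume, target_shape: tuple[int, int, int], mode: str = "linear"
) -> ImageVolume:
    """Resample a volume to a fixed grid shape, preserving physical extent.

    The output voxel size is ``spacing_i * dim_i / target_dim_i`` per axis, and
    the grids share their outer physical bounding box: output voxel centres are
    placed inside the input's voxel-face extent, so the extent is preserved to
    within half an output voxel on every axis.
    """
    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != 3 or min(target_shape) < 1:
        raise ValueError(f"target_shape must be 3 positive ints, got {target_shape}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")

    in_shape = np.array(volume.shape, dtype=np.float64)
    out_shape = np.array(target_shape, dtype=np.float64)
    out_spacing = volume.spacing * in_shape / out_shape
    # Outer extent alignment: first output centre sits half an output voxel
    # inside the extent start (= origin - spacing/2).
    out_origin = volume.origin - volume.spacing / 2 + out_spacing / 2

    # Output centre j maps to input index (out_origin + j*out_spacing - origin)/spacing.
    grids = [
        (out_origin[a] + np.arange(target_shape[a]) * out_spacing[a] - volume.origin[a])
        / volume.spacing[a]
        for a in range(3)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    order = 1 if mode == "linear" else 0
    data = ndimage.map_coordinates(
        volume.data.astype(np.float32), np.array(coords), order=order, mode="nearest"
    )
    out = volume.copy_with(data=data, spacing=out_spacing, origin=out_origin)
    return out


def resample_mask_to_shape(mask: BinaryMask, target_shape: tuple[int, int, int]) -> BinaryMask:
    """Resample a binary mask via trilinear interpolation then 0.5 threshold.

    Thresholded trilinear interpolation avoids the aliasing holes that pure
    nearest-neighbour downsampling punches through thin cortical shells.
    """
    as_vol = ImageVolume(mask.data.astype(np.float32), mask.spacing, mask.origin)
    res = resample_to_shape(as_vol, target_shape, mode="linear")
    return BinaryMask(data=res.data >= 0.5, spacing=res.spacing, origin=res.origin)


def crop_to_box(volume: ImageVolume, box) -> ImageVolume:
    """Crop to ``box = ((x0, x1), (y0, y1), (z0, z1))`` with exclusive stops.

    The origin shifts by ``start * spacing``; spacing is unchanged.
    """
    box = tuple((int(lo), int(hi)) for lo, hi in box)
    for axis, (lo, hi) in enumerate(box):
        if not (0 <= lo < hi <= volume.shape[axis]):
            raise IndexError(
                f"box {box} out of bounds or empty for shape {volume.shape} (axis {axis})"
            )
    sl = tuple(slice(lo, hi) for lo, hi in box)
    start = np.array([b[0] for b in box], dtype=np.float64)
    new_origin = volume.origin + start * volume.spacing
    return volume.copy_with(data=volume.data[sl].copy(), origin=new_origin)
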