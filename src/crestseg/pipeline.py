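"""Two-stage coarse-to-fine segmentation and mesh post-processing.

Stage 1 segments the bone from the whole field of view at a fixed coarse
grid (default 160 x 160 x 224); a region of interest is cropped around the
stage-1 result and stage 2 re-segments that crop at a higher relative
resolution (default 256 x 144 x 144). The binary stage-2 output is then
turned into a surgical-planning mesh: one layer of binary erosion (which
compensates for the dilation built into the greedy training masks), Gaussian
smoothing of the {0,1} field, and marching cubes. Disconnected fragments
are deliberately kept.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh
from scipy import ndimage

from . import grid, meshes, unet


class BoneNotFoundError(RuntimeError):
    """No voxel exceeded the binarization threshold."""


@dataclasses.dataclass
class PipelineConfig:
    stage1_shape: tuple[int, int, int] = (160, 160, 224)
    stage2_shape: tuple[int, int, int] = (256, 144, 144)
    binarize_threshold: float = 0.5
    roi_margin: float = 0.05
    erosion_iterations: int = 1
    gaussian_sigma: float = 1.0
    iso_value: float = 0.5
    hu_window: tuple[float, float] = grid.DEFAULT_HU_WINDOW

    def __post_init__(self):
        for shape in (self.stage1_shape, self.stage2_shape):
            if any(s % 16 for s in shape):
                raise ValueError(f"stage shape {shape} not divisible by 16")
        if not 0 < self.binarize_threshold < 1:
            raise ValueError("binarize_threshold must be in (0, 1)")
        if self.roi_margin < 0:
            raise ValueError("roi_margin must be >= 0")


@dataclasses.dataclass
class SegmentationResult:
    stage1_mask: grid.BinaryMask
    roi_box: tuple
    stage2_mask: grid.BinaryMask
    mesh: trimesh.Trimesh


def stage1_segment(ct: grid.ImageVolume, net1: unet.UNet3D,
                   config: PipelineConfig) -> grid.BinaryMask:
    """Whole-field segmentation at the stage-1 grid."""
    x = grid.resample_to_shape(
        grid.normalize_intensities(ct, config.hu_window), config.stage1_shape, "linear"
    )
    prob = net1.forward(x.data)
    binary = prob > config.binarize_threshold
    if not binary.any():
        raise BoneNotFoundError("stage 1 found no voxel above threshold")
    return grid.BinaryMask(data=binary, spacing=x.spacing, origin=x.origin)


def roi_from_mask(mask: grid.BinaryMask, ct: grid.ImageVolume,
                  margin: float = 0.05) -> tuple:
    """Native-CT index box around the stage-1 foreground, expanded by margin.

    The tight stage-1 voxel bounding box is mapped through the stage-to-native
    scaling (stage voxel i covers native indices [i*s, (i+1)*s)), expanded by
    ``margin`` of its extent per side, and clamped to the volume bounds.
    """
    idx = np.nonzero(mask.data)
    if idx[0].size == 0:
        raise ValueError("empty stage-1 mask")
    box = []
    for axis in range(3):
        scale = ct.shape[axis] / mask.shape[axis]
        lo = int(np.floor(idx[axis].min() * scale))
        hi = int(np.ceil((idx[axis].max() + 1) * scale))
        pad = int(np.ceil((hi - lo) * margin))
        box.append((max(0, lo - pad), min(ct.shape[axis], hi + pad)))
    return tuple(box)


def stage2_segment(ct: grid.ImageVolume, roi_box, net2: unet.UNet3D,
                   config: PipelineConfig) -> grid.BinaryMask:
    """Segment the cropped ROI at the stage-2 grid (crop geometry kept)."""
    crop = grid.crop_to_box(grid.normalize_intensities(ct, config.hu_window), roi_box)
    x = grid.resample_to_shape(crop, config.stage2_shape, "linear")
    prob = net2.forward(x.data)
    binary = prob > config.binarize_threshold
    if not binary.any():
        raise BoneNotFoundError("stage 2 found no voxel above threshold")
    return grid.BinaryMask(data=binary, spacing=x.spacing, origin=x.origin)


def postprocess(mask: grid.BinaryMask, config: PipelineConfig) -> trimesh.Trimesh:
    """Erosion -> Gaussian smoothing -> marching cubes, keeping all fragments.

    The structuring element is the 6-connected cross ("about one layer of
    voxels"); voxels outside the grid count as background. An empty
    post-erosion mask yields an empty mesh.
    """
    data = mask.data
    if config.erosion_iterations > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        data = ndimage.binary_erosion(
            data, structure=struct, iterations=config.erosion_iterations,
            border_value=0,
        )
    if not data.any():
        return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))
    field = ndimage.gaussian_filter(data.astype(np.float32), sigma=config.gaussian_sigma)
    return meshes.marching_cubes(field, config.iso_value, mask.spacing, mask.origin)


def run_pipeline(ct: grid.ImageVolume, net1: unet.UNet3D, net2: unet.UNet3D,
                 config: PipelineConfig | None = None) -> SegmentationResult:
    """Full two-stage inference; deterministic given weights and input."""
    config = config or PipelineConfig()
    s1 = stage1_segment(ct, net1, config)
    roi_box = roi_from_mask(s1, ct, config.roi_margin)
    s2 = stage2_segment(ct, roi_box, net2, config)
    mesh = postprocess(s2, config)
    return SegmentationResult(stage1_mask=s1, roi_box=roi_box, stage2_mask=s2, mesh=mesh)
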