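"""Transplant-relevant region of interest via a recorded cutting plane.

The crest region used for harvesting is delimited on a reference bone by an
oblique plane. The plane is stored relative to the bone's geometric centre:
the anchor offset is divided componentwise by the mesh bounding-box
half-extents (``scaled`` mode, the default), so the plane lands at an
anatomically comparable position on bones of different size; ``translate``
mode stores the raw mm offset and only re-centres on the target. Left and
right crest definitions are mirror images across the mid-sagittal (first)
axis.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import trimesh

from .meshes import CuttingPlane, clip_by_plane, geometric_center


@dataclasses.dataclass
class RoiDefinition:
    """A cutting plane in mesh-relative normalized coordinates."""

    anchor: np.ndarray          # offset from geometric centre, normalized
    normal: np.ndarray          # unit, absolute orientation
    side: str                   # "left" | "right"
    mode: str = "scaled"        # "scaled" | "translate"

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, dtype=np.float64).reshape(3)
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        self.normal = self.normal / np.linalg.norm(self.normal)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.mode not in ("scaled", "translate"):
            raise ValueError(f"mode must be 'scaled' or 'translate', got {self.mode!r}")
        if self.mode == "scaled" and np.any(np.abs(self.anchor) > 2.0):
            raise ValueError(f"normalized anchor {self.anchor} outside sanity bound [-2, 2]")

    def to_json(self, path=None) -> str:
        payload = {
            "anchor": self.anchor.tolist(),
            "normal": self.normal.tolist(),
            "side": self.side,
            "mode": self.mode,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RoiDefinition":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


def _half_extents(mesh: trimesh.Trimesh) -> np.ndarray:
    bounds = mesh.bounds
    half = (bounds[1] - bounds[0]) / 2.0
    if np.any(half <= 0):
        raise ValueError("mesh is degenerate along at least one axis")
    return half


def record_roi(reference_mesh: trimesh.Trimesh, plane: CuttingPlane, side: str,
               mode: str = "scaled") -> RoiDefinition:
    """Record an absolute cutting plane relative to a reference bone."""
    signed = (reference_mesh.bounding_box.vertices - plane.anchor) @ plane.normal
    if signed.min() > 0 or signed.max() < 0:
        raise ValueError("plane does not intersect the mesh bounding box")
    center = geometric_center(reference_mesh)
    offset = plane.anchor - center
    if mode == "scaled":
        offset = offset / _half_extents(reference_mesh)
    return RoiDefinition(anchor=offset, normal=plane.normal, side=side, mode=mode)


def absolute_plane(target_mesh: trimesh.Trimesh, roi: RoiDefinition) -> CuttingPlane:
    """Reconstruct the absolute cutting plane on a target bone."""
    center = geometric_center(target_mesh)
    offset = roi.anchor
    if roi.mode == "scaled":
        offset = offset * _half_extents(target_mesh)
    return CuttingPlane(anchor=center + offset, normal=roi.normal)


def apply_roi(target_mesh: trimesh.Trimesh, roi: RoiDefinition) -> trimesh.Trimesh:
    """Clip the target mesh to the crest side of the reconstructed plane.

    Returns an empty mesh (flagged by ``len(mesh.faces) == 0``) when nothing
    lies on the kept side.
    """
    if len(target_mesh.faces) == 0:
        raise ValueError("cannot apply an ROI to an empty mesh")
    return clip_by_plane(target_mesh, absolute_plane(target_mesh, roi))


def mirror_roi(roi: RoiDefinition) -> RoiDefinition:
    """Reflect a crest definition across the mid-sagittal axis, flipping side."""
    flip = np.array([-1.0, 1.0, 1.0])
    return RoiDefinition(
        anchor=roi.anchor * flip,
        normal=roi.normal * flip,
        side="right" if roi.side == "left" else "left",
        mode=roi.mode,
    )
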