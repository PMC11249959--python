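"""Spherical regions of interest in world coordinates.

The ALPS scheme uses four 5 mm spheres at the level of the lateral
ventricle bodies: projection and association fibre regions in each
hemisphere.  Centers are given in world (RAS) millimetres; a voxel
belongs to a sphere when its center point lies within the radius
(boundary included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ROI_LABELS = (
    "projection_left",
    "projection_right",
    "association_left",
    "association_right",
)

# expected dominant fibre axis per region (world axis index): projection
# fibres run head-foot (z), association fibres anterior-posterior (y)
EXPECTED_AXIS = {"projection": 2, "association": 1}


class EmptyROIError(ValueError):
    """Sphere does not intersect the voxel grid."""


@dataclass(frozen=True)
class SphereROI:
    label: str
    center: tuple[float, float, float]
    radius: float = 5.0

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.label!r}; expected one of {ROI_LABELS}")
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")
        x = self.center[0]
        if self.label.endswith("_left") and not x < 0:
            raise ValueError(f"{self.label}: left-hemisphere center must have x < 0 (RAS), got x={x}")
        if self.label.endswith("_right") and not x > 0:
            raise ValueError(f"{self.label}: right-hemisphere center must have x > 0 (RAS), got x={x}")

    @property
    def fiber_type(self) -> str:
        return self.label.split("_")[0]

    @property
    def hemisphere(self) -> str:
        return self.label.split("_")[1]


@dataclass(frozen=True)
class ROISet:
    """Exactly one sphere per ALPS label."""

    rois: tuple[SphereROI, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if sorted(labels) != sorted(ROI_LABELS):
            raise ValueError(
                f"ROISet needs exactly the four labels {ROI_LABELS}, got {labels}"
            )
        for hemi in ("left", "right"):
            proj = self[f"projection_{hemi}"].center
            assoc = self[f"association_{hemi}"].center
            if np.allclose(proj, assoc):
                raise ValueError(f"projection and association centers coincide in {hemi} hemisphere")

    def __getitem__(self, label: str) -> SphereROI:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)

    def __iter__(self):
        return iter(self.rois)

    @classmethod
    def from_dict(cls, blocks: list[dict]) -> "ROISet":
        return cls(tuple(
            SphereROI(label=b["label"], center=tuple(b["center"]),
                      radius=float(b.get("radius", 5.0)))
            for b in blocks
        ))

    def to_dict(self) -> list[dict]:
        return [{"label": r.label, "center": list(r.center), "radius": r.radius}
                for r in self.rois]

    def mirrored(self) -> "ROISet":
        """Reflect all centers across the mid-sagittal plane, swapping hemispheres."""
        swapped = []
        for r in self.rois:
            hemi = "right" if r.hemisphere == "left" else "left"
            swapped.append(SphereROI(
                label=f"{r.fiber_type}_{hemi}",
                center=(-r.center[0], r.center[1], r.center[2]),
                radius=r.radius,
            ))
        return ROISet(tuple(swapped))


def rasterize_sphere(roi: SphereROI, affine: np.ndarray,
                     shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean mask of voxels whose world-space centers fall inside the sphere.

    Restricted to the sphere's bounding box in voxel space for speed;
    membership is the exact Euclidean test against voxel-center points.
    """
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    center_vox = (inv @ np.append(roi.center, 1.0))[:3]
    # conservative per-axis half-width of the bounding box in voxel units
    spacing = np.linalg.norm(inv[:3, :3], axis=1) * roi.radius
    lo = np.maximum(np.floor(center_vox - spacing - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + spacing + 1).astype(int) + 1, shape)

    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        raise EmptyROIError(f"{roi.label}: sphere at {roi.center} lies outside the grid")
    ii, jj, kk = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    inside = np.linalg.norm(world - np.asarray(roi.center), axis=1) <= roi.radius
    mask[vox[inside, 0], vox[inside, 1], vox[inside, 2]] = True
    if not mask.any():
        raise EmptyROIError(f"{roi.label}: no voxel center within {roi.radius} mm of {roi.center}")
    return mask
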