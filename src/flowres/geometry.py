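"""Threshold lumen segmentation and the geometric plane measurements.

The magnitude channel of a 4D-flow acquisition carries the lumen
partial-volume fraction per voxel; segmentation is a plain threshold on it.
The coarse-resolution geometry bias of the study follows directly: with a
permissive threshold, rim voxels that are only fractionally inside the
vessel are counted as lumen, and the area they add grows with voxel size,
inflating the equivalent diameter of coarse scans.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import EmptyRegionError
from .virtual_scanner import Voxel4DFlow

__all__ = [
    "PlaneRole",
    "PlaneSpec",
    "LumenMask",
    "segment",
    "slice_area",
    "equivalent_diameter",
    "save_mask_nifti",
    "load_mask_nifti",
]


class PlaneRole(str, enum.Enum):
    INLET = "inlet"
    MID_VESSEL = "mid_vessel"


@dataclass(frozen=True)
class PlaneSpec:
    """An analysis plane perpendicular to the vessel (y) axis.

    axis_coordinate is the plane position in metres along y; the plane maps
    to the voxel slice whose half-open interval [y_j, y_j + h) contains it.
    """

    axis_coordinate: float
    role: PlaneRole = PlaneRole.MID_VESSEL


@dataclass
class LumenMask:
    """Boolean lumen labelling on the grid of its source acquisition."""

    mask: np.ndarray  # (nx, ny, nz) bool
    origin: np.ndarray
    voxel_size: float  # mm
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def voxel_size_m(self) -> float:
        return self.voxel_size * 1e-3

    def slice_index(self, plane: PlaneSpec) -> int:
        """Voxel slice (along y) containing the plane's axis coordinate."""
        j = int(np.floor((plane.axis_coordinate - self.origin[1]) / self.voxel_size_m))
        if not 0 <= j < self.mask.shape[1]:
            raise EmptyRegionError(
                f"plane at y={plane.axis_coordinate} m lies outside the grid"
            )
        return j

    def slice_mask(self, plane: PlaneSpec) -> np.ndarray:
        """(nx, nz) boolean in-plane lumen mask; errors if empty."""
        sl = self.mask[:, self.slice_index(plane), :]
        if not sl.any():
            raise EmptyRegionError("no lumen voxels in the requested slice")
        return sl


def segment(vox: Voxel4DFlow, threshold: float = 0.25) -> LumenMask:
    """Threshold the magnitude channel into a lumen mask.

    A voxel is lumen when its partial-volume magnitude is >= threshold.
    The magnitude channel already encodes the maximum (peak-systolic) vessel
    extent, so the returned mask is the maximum-extent mask over frames.
    The default threshold of 0.25 accepts rim voxels with as little as a
    quarter lumen coverage, which reproduces the dilation of coarse scans;
    use 0.5 for an asymptotically unbiased boundary.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return LumenMask(
        mask=vox.magnitude >= threshold,
        origin=vox.origin,
        voxel_size=vox.voxel_size,
        threshold=threshold,
    )


def slice_area(mask: LumenMask, plane: PlaneSpec) -> float:
    """Lumen cross-section area of the plane's voxel slice in m^2.

    area = (number of lumen voxels in the slice) * voxel_size^2.
    """
    sl = mask.slice_mask(plane)
    return float(sl.sum()) * mask.voxel_size_m**2


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the same area: d = 2 sqrt(area / pi)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return 2.0 * np.sqrt(area / np.pi)


def save_mask_nifti(mask: LumenMask, path) -> None:
    """Write the mask as uint8 NIfTI (voxel size in mm in the affine)."""
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] *= mask.voxel_size
    affine[:3, 3] = mask.origin * 1e3
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), path)


def load_mask_nifti(path, threshold: float = float("nan")) -> LumenMask:
    import nibabel as nib

    img = nib.load(path)
    voxel_size = float(img.affine[0, 0])
    return LumenMask(
        mask=np.asarray(img.dataobj) > 0,
        origin=img.affine[:3, 3] * 1e-3,
        voxel_size=voxel_size,
        threshold=threshold,
    )
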