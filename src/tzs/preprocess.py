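"""Abdominopelvic region extraction and bounding-box registration.

The body region of interest (ROI) is recovered by thresholding (Otsu by
default), one pass of binary closing, and keeping the largest 6-connected
foreground component — yielding an anatomical bounding box with minimal void
around the body. ROIs of different scans are registered with an axis-aligned
affine map (per-axis scale + translation); bounding boxes carry no rotation
information, so this transform is exactly determined by the two ROIs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .boxes import Box

__all__ = [
    "Volume3D",
    "AffineMap",
    "extract_body_roi",
    "fit_roi_affine",
    "apply_affine_box",
]


@dataclass(frozen=True)
class Volume3D:
    """A 3D intensity grid with per-axis voxel spacing in millimetres."""

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError("volume must be 3D")
        if min(arr.shape) < 8:
            raise ValueError("every axis must have at least 8 voxels")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or min(spacing) <= 0:
            raise ValueError("spacing must be 3 positive values (mm)")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def bounds(self) -> Box:
        return Box(np.zeros(3), np.asarray(self.shape, dtype=float))


@dataclass(frozen=True)
class AffineMap:
    """Axis-aligned affine ``p -> p * scale + offset`` between voxel frames."""

    scale: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        scale = np.asarray(self.scale, dtype=float).reshape(3)
        offset = np.asarray(self.offset, dtype=float).reshape(3)
        if np.any(scale <= 0):
            raise ValueError("scale must be positive on every axis")
        object.__setattr__(self, "scale", scale)
        object.__setattr__(self, "offset", offset)

    def apply_point(self, point) -> np.ndarray:
        return np.asarray(point, dtype=float) * self.scale + self.offset

    def inverse(self) -> "AffineMap":
        return AffineMap(1.0 / self.scale, -self.offset / self.scale)


def extract_body_roi(volume: Volume3D, threshold: float | None = None) -> Box:
    """Tight bounding box of the body.

    Voxels ``>= threshold`` (Otsu when None) are closed once with the
    6-connected structuring element, then the largest 6-connected component
    is kept and its tight bounding box returned.

    Raises ``ValueError`` ("empty body mask") when nothing passes threshold.
    """
    data = volume.intensities
    if threshold is None:
        if np.ptp(data) == 0:
            raise ValueError("empty body mask: constant volume")
        threshold = float(threshold_otsu(np.asarray(data, dtype=float)))
    mask = data >= threshold
    if not mask.any():
        raise ValueError("empty body mask: no voxel reaches threshold")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    mask = ndimage.binary_closing(mask, structure=structure)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        raise ValueError("empty body mask after closing")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    return Box.from_mask(labels == largest)


def fit_roi_affine(source: Box, reference: Box) -> AffineMap:
    """The axis-aligned affine sending the source ROI exactly onto the
    reference ROI (corners onto corners)."""
    src_extent = source.extent
    ref_extent = reference.extent
    if np.any(src_extent <= 0) or np.any(ref_extent <= 0):
        raise ValueError("degenerate ROI box")
    scale = ref_extent / src_extent
    offset = reference.lo - source.lo * scale
    return AffineMap(scale, offset)


def apply_affine_box(affine: AffineMap, box: Box, clip_to: Box | None = None) -> Box | None:
    """Transform a box's corners, re-sorting min/max per axis.

    When ``clip_to`` is given (the reference bounds) the result is clipped;
    a box falling entirely outside returns None.
    """
    a = affine.apply_point(box.lo)
    b = affine.apply_point(box.hi)
    out = Box(np.minimum(a, b), np.maximum(a, b))
    if clip_to is not None:
        return out.clipped(clip_to)
    return out
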