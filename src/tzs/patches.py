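"""ROI partitioning, patch labels, extraction/resampling, augmentation, splits.

The abdominopelvic ROI is tiled by a k x k x k grid of contiguous patches.
A patch is positive iff it contains the center of at least one annotation
box, so a single-TZ scan yields exactly one positive patch out of k^3.
Patches are resampled to a fixed cubic side with trilinear interpolation
before classification.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .boxes import Box
from .preprocess import Volume3D

__all__ = [
    "PatchGrid",
    "PatchSample",
    "AugmentParams",
    "partition_roi",
    "label_patches",
    "extract_resize_patch",
    "augment_patch",
    "split_patients",
]


@dataclass(frozen=True)
class PatchGrid:
    """The k^3 partition of an ROI: per axis, k contiguous intervals whose
    lengths differ by at most one voxel (remainders go to the lowest-index
    intervals)."""

    roi: Box
    k: int
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]

    @property
    def n_patches(self) -> int:
        return self.k ** 3

    def flat_index(self, i: int, j: int, l: int) -> int:
        return (i * self.k + j) * self.k + l

    def unravel(self, flat: int) -> tuple[int, int, int]:
        i, rest = divmod(flat, self.k * self.k)
        j, l = divmod(rest, self.k)
        return i, j, l

    def bounds(self, flat: int) -> Box:
        i, j, l = self.unravel(flat)
        lo = np.array([self.edges[0][i], self.edges[1][j], self.edges[2][l]], dtype=float)
        hi = np.array(
            [self.edges[0][i + 1], self.edges[1][j + 1], self.edges[2][l + 1]], dtype=float
        )
        return Box(lo, hi)

    def all_bounds(self) -> list[Box]:
        return [self.bounds(f) for f in range(self.n_patches)]

    def centers(self) -> np.ndarray:
        """(k^3, 3) array of patch center points."""
        return np.stack([self.bounds(f).center for f in range(self.n_patches)])

    def index_of(self, point, clamp: bool = False) -> int:
        """Flat patch index of a (z,y,x) point.

        Points exactly on a shared interior boundary plane go to the
        lower-index patch, matching the region-grid thirds convention. With
        ``clamp`` a point outside the ROI is clamped to the nearest interior
        position (with a warning), mirroring how off-ROI annotation centers
        are handled.
        """
        p = np.asarray(point, dtype=float).reshape(3).copy()
        if not self.roi.contains(p):
            if not clamp:
                raise ValueError(f"point {p.tolist()} outside ROI")
            warnings.warn(f"point {p.tolist()} outside ROI; clamped", stacklevel=2)
            eps = 1e-9
            p = np.minimum(np.maximum(p, self.roi.lo), self.roi.hi - eps)
        idx3 = []
        for ax in range(3):
            i = int(np.searchsorted(self.edges[ax], p[ax], side="left")) - 1
            idx3.append(min(max(i, 0), self.k - 1))
        return self.flat_index(*idx3)


@dataclass
class PatchSample:
    """One classifier example: a resampled cubic patch plus bookkeeping.

    ``bounds`` (native-frame patch box) is kept so positive samples can be
    re-extracted under augmentation.
    """

    intensities: np.ndarray
    label: int
    scan_id: str
    patch_index: tuple[int, int, int]
    bounds: Box | None = None


@dataclass(frozen=True)
class AugmentParams:
    """Positive-patch augmentation: per-axis translation uniform on
    [-max_translation_mm, +max_translation_mm] and window zoom uniform on
    ``zoom_range``."""

    max_translation_mm: float = 30.0
    zoom_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_translation_mm < 0:
            raise ValueError("max_translation_mm must be >= 0")
        lo, hi = self.zoom_range
        if not (0 < lo <= hi):
            raise ValueError("zoom_range must be positive and ordered")


def _axis_edges(lo: float, hi: float, k: int) -> np.ndarray:
    extent = int(round(hi - lo))
    base, rem = divmod(extent, k)
    lengths = [base + 1 if i < rem else base for i in range(k)]
    return np.concatenate([[lo], lo + np.cumsum(lengths)])


def partition_roi(roi: Box, k: int) -> PatchGrid:
    """Split the ROI into k^3 patches tiling it exactly."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.any(roi.extent < k):
        raise ValueError(f"ROI extent {roi.extent.tolist()} too small for k={k}")
    edges = tuple(_axis_edges(roi.lo[ax], roi.hi[ax], k) for ax in range(3))
    return PatchGrid(roi=roi, k=k, edges=edges)


def label_patches(grid: PatchGrid, boxes: list[Box]) -> np.ndarray:
    """Binary label per patch: 1 iff >= 1 box center lies in the patch."""
    labels = np.zeros(grid.n_patches, dtype=np.int8)
    for box in boxes:
        labels[grid.index_of(box.center, clamp=True)] = 1
    return labels


def extract_resize_patch(
    volume: Volume3D,
    bounds: Box,
    patch_side: int,
    norm_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Trilinearly resample the patch sub-volume to ``patch_side^3``.

    Sampling positions are corner-aligned (``linspace(lo, hi-1, side)`` per
    axis), which keeps trilinear interpolation exact on affine intensity
    fields. When ``norm_range`` — typically the scan's body-mask 1st/99th
    intensity percentiles — is given, output is linearly rescaled to [0, 1]
    and clipped.
    """
    if patch_side < 2:
        raise ValueError("patch_side must be >= 2")
    if np.any(bounds.extent < 1):
        raise ValueError("degenerate patch bounds")
    axes = [np.linspace(bounds.lo[ax], bounds.hi[ax] - 1.0, patch_side) for ax in range(3)]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(volume.intensities, dtype=float),
        np.stack([c.ravel() for c in coords]),
        order=1,
        mode="nearest",
    ).reshape(patch_side, patch_side, patch_side)
    if norm_range is not None:
        lo, hi = norm_range
        if hi > lo:
            out = np.clip((out - lo) / (hi - lo), 0.0, 1.0)
        else:
            out = np.zeros_like(out)
    return out.astype(np.float32)


def augment_patch(
    sample: PatchSample,
    params: AugmentParams,
    volume: Volume3D,
    norm_range: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> PatchSample:
    """Re-extract a positive patch from a randomly shifted and zoomed window.

    The source window is translated by a per-axis uniform draw within
    ±max_translation_mm (converted to voxels by the scan spacing) and its
    extent scaled by a uniform zoom factor. Only positive samples may be
    augmented; the stored label is preserved.
    """
    if sample.label != 1:
        raise ValueError("augmentation is applied to positive patches only")
    if sample.bounds is None:
        raise ValueError("sample carries no source bounds; cannot re-extract")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    spacing = np.asarray(volume.spacing_mm)
    shift_vox = rng.uniform(-params.max_translation_mm, params.max_translation_mm, 3) / spacing
    zoom = rng.uniform(params.zoom_range[0], params.zoom_range[1])
    center = sample.bounds.center + shift_vox
    half = sample.bounds.extent * zoom / 2.0
    window = Box(center - half, center + half)
    side = sample.intensities.shape[0]
    out = extract_resize_patch(volume, window, side, norm_range=norm_range)
    return PatchSample(
        intensities=out,
        label=sample.label,
        scan_id=sample.scan_id,
        patch_index=sample.patch_index,
        bounds=sample.bounds,
    )


def split_patients(
    patient_ids,
    proportions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> tuple[set, set, set]:
    """Patient-level train/validation/test split with no overlap.

    Validation and test sizes are ``round(n * p)``; the remainder goes to
    training, so 1000 patients at (0.7, 0.2, 0.1) give exactly 700/200/100.
    """
    ids = sorted(set(patient_ids))
    n = len(ids)
    if n < 3:
        raise ValueError("need at least as many patients as sets")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(round(n * proportions[1]))
    n_test = int(round(n * proportions[2]))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("split leaves an empty set; need more patients")
    shuffled = [ids[i] for i in order]
    train = set(shuffled[:n_train])
    val = set(shuffled[n_train : n_train + n_val])
    test = set(shuffled[n_train + n_val :])
    return train, val, test
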