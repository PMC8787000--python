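"""Spatial prior of transition-zone location.

Three related objects live here:

* the nine classical abdominal regions, defined as a coronal 3x3 grid over
  the abdominopelvic ROI (equal thirds on the cranio-caudal z axis and the
  right-left x axis; the anterior-posterior y axis is ignored);
* the cohort heatmap, the per-voxel count of scans whose registered
  annotation boxes cover that voxel of the reference frame;
* the per-patch prior, the fraction of training scans with at least one
  registered TZ box center inside the patch, floored at a small constant so
  no patch is ever irrecoverably suppressed after score coupling.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .boxes import Box
from .patches import PatchGrid

__all__ = [
    "REGION_LABELS",
    "Heatmap",
    "PatchPrior",
    "assign_region",
    "region_histogram",
    "build_heatmap",
    "compute_patch_prior",
]

# Row-major 3x3 coronal grid: rows follow z (cranial -> caudal), columns
# follow x (patient-right -> patient-left).
_REGION_GRID: tuple[tuple[str, str, str], ...] = (
    ("right hypochondriac", "epigastric", "left hypochondriac"),
    ("right lumbar", "umbilical", "left lumbar"),
    ("right iliac", "hypogastric", "left iliac"),
)

REGION_LABELS: tuple[str, ...] = tuple(lbl for row in _REGION_GRID for lbl in row)


def _third(coord: float, lo: float, hi: float) -> int:
    """Index of the third (0, 1, 2) containing ``coord`` in [lo, hi).

    Points exactly on an interior boundary go to the lower-index third.
    """
    f = (coord - lo) / (hi - lo)
    idx = int(np.ceil(3.0 * f)) - 1
    return min(max(idx, 0), 2)


def assign_region(point, roi: Box) -> str:
    """Assign a (z, y, x) point inside ``roi`` to one of the nine regions."""
    p = np.asarray(point, dtype=float).reshape(3)
    if np.any(p < roi.lo) or np.any(p >= roi.hi):
        raise ValueError(f"point {p.tolist()} outside ROI")
    row = _third(p[0], roi.lo[0], roi.hi[0])
    col = _third(p[2], roi.lo[2], roi.hi[2])
    return _REGION_GRID[row][col]


def region_histogram(points, roi: Box) -> dict[str, float]:
    """Percentage of points per region; percentages sum to 100."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("at least one point required")
    counts = {label: 0 for label in REGION_LABELS}
    for p in points:
        counts[assign_region(p, roi)] += 1
    n = points.shape[0]
    return {label: 100.0 * counts[label] / n for label in REGION_LABELS}


@dataclass(frozen=True)
class Heatmap:
    """Per-voxel count, over the reference ROI, of scans whose registered TZ
    boxes cover the voxel."""

    counts: np.ndarray
    n_scans: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError("heatmap counts must be 3D")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if counts.min() < 0 or counts.max() > self.n_scans:
            raise ValueError("counts must lie in [0, n_scans]")
        object.__setattr__(self, "counts", counts)

    @property
    def normalized(self) -> np.ndarray:
        return self.counts / float(self.n_scans)


def build_heatmap(boxes_per_scan: list[list[Box]], reference: Box) -> Heatmap:
    """Sum per-scan box-union indicators over the reference ROI.

    ``boxes_per_scan`` holds, per scan, its annotation boxes already
    registered into the reference frame. Each scan contributes at most 1 per
    voxel (the indicator of the union of its boxes). Boxes entirely outside
    the reference trigger a warning and contribute nothing.
    """
    if len(boxes_per_scan) == 0:
        raise ValueError("at least one scan required")
    shape = tuple(int(v) for v in np.rint(reference.extent))
    counts = np.zeros(shape, dtype=np.int32)
    origin = reference.lo
    for scan_idx, boxes in enumerate(boxes_per_scan):
        indicator = np.zeros(shape, dtype=bool)
        for box in boxes:
            shifted = Box(box.lo - origin, box.hi - origin)
            clipped = shifted.clipped(Box(np.zeros(3), np.asarray(shape, dtype=float)))
            if clipped is None:
                warnings.warn(
                    f"scan {scan_idx}: registered box entirely outside reference; ignored",
                    stacklevel=2,
                )
                continue
            indicator[clipped.rounded().voxel_slices()] = True
        counts += indicator
    return Heatmap(counts, len(boxes_per_scan))


@dataclass(frozen=True)
class PatchPrior:
    """Per-patch probability that a scan's TZ center falls in the patch."""

    k: int
    prob: np.ndarray
    floor: float

    def __post_init__(self) -> None:
        prob = np.asarray(self.prob, dtype=float)
        if prob.shape != (self.k ** 3,):
            raise ValueError(f"prior must have k^3 = {self.k ** 3} entries")
        if prob.min() < self.floor - 1e-12 or prob.max() > 1.0 + 1e-12:
            raise ValueError("prior entries must lie in [floor, 1]")
        object.__setattr__(self, "prob", prob)


def compute_patch_prior(
    centers_per_scan: list[list[np.ndarray]],
    grid: PatchGrid,
    floor: float = 1e-3,
) -> PatchPrior:
    """Estimate the patch prior from registered training box centers.

    Each training scan counts once per patch (closed-loop scans with two
    centers in one patch do not double-weight it):
    ``prob = #scans with >= 1 center in patch / #scans``, floored.
    """
    n_scans = len(centers_per_scan)
    if n_scans == 0:
        raise ValueError("empty training set")
    hits = np.zeros(grid.k ** 3, dtype=np.int64)
    for centers in centers_per_scan:
        patch_ids = {grid.index_of(c, clamp=True) for c in centers}
        for idx in patch_ids:
            hits[idx] += 1
    prob = np.maximum(hits / float(n_scans), floor)
    return PatchPrior(grid.k, prob, floor)
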