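"""Axis-aligned boxes in voxel coordinates.

Conventions used throughout the package:

* axis order is ``(z, y, x)`` — z cranio-caudal increasing caudally,
  y anterior-posterior, x increasing toward patient-left;
* coordinates are 0-based voxel indices;
* boxes are half-open: a voxel ``v`` is inside iff ``lo <= v < hi``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Box"]


@dataclass(frozen=True)
class Box:
    """An axis-aligned half-open box ``[lo, hi)`` in (z, y, x) voxel coordinates.

    Corners are stored as float so that registered (affine-mapped) boxes keep
    sub-voxel precision; integer-valued boxes index arrays directly via
    :meth:`voxel_slices`.
    """

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float).reshape(3)
        hi = np.asarray(self.hi, dtype=float).reshape(3)
        if not np.all(lo < hi):
            raise ValueError(f"degenerate box: lo={lo.tolist()} hi={hi.tolist()}")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    # -- geometry -----------------------------------------------------------
    @property
    def extent(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def center(self) -> np.ndarray:
        return (self.lo + self.hi) / 2.0

    @property
    def volume(self) -> float:
        return float(np.prod(self.extent))

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float).reshape(3)
        return bool(np.all(p >= self.lo) and np.all(p < self.hi))

    def clipped(self, bounds: "Box") -> "Box | None":
        """Intersection with ``bounds``, or None when empty."""
        lo = np.maximum(self.lo, bounds.lo)
        hi = np.minimum(self.hi, bounds.hi)
        if np.any(lo >= hi):
            return None
        return Box(lo, hi)

    # -- voxel indexing -----------------------------------------------------
    def rounded(self) -> "Box":
        """Nearest-integer corners (used when a registered float box must
        index the reference grid)."""
        lo = np.rint(self.lo)
        hi = np.rint(self.hi)
        hi = np.maximum(hi, lo + 1)  # keep at least one voxel
        return Box(lo, hi)

    def voxel_slices(self) -> tuple[slice, slice, slice]:
        lo = np.asarray(np.floor(self.lo), dtype=int)
        hi = np.asarray(np.ceil(self.hi), dtype=int)
        return tuple(slice(a, b) for a, b in zip(lo, hi))

    # -- (de)serialisation ---------------------------------------------------
    def as_list(self) -> list[float]:
        """``[zmin, ymin, xmin, zmax, ymax, xmax]`` (half-open)."""
        out = [*self.lo.tolist(), *self.hi.tolist()]
        return [int(v) if float(v).is_integer() else float(v) for v in out]

    @classmethod
    def from_list(cls, values) -> "Box":
        values = list(values)
        if len(values) != 6:
            raise ValueError("box list must have 6 entries [zmin,ymin,xmin,zmax,ymax,xmax]")
        return cls(np.asarray(values[:3], dtype=float), np.asarray(values[3:], dtype=float))

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "Box":
        """Tight bounding box of the True voxels of a 3D mask."""
        if mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not mask.any():
            raise ValueError("empty mask has no bounding box")
        idx = np.argwhere(mask)
        return cls(idx.min(axis=0).astype(float), idx.max(axis=0).astype(float) + 1.0)
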