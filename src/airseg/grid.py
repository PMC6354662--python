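"""Core grid types: scalar volumes and boolean masks on axis-aligned voxel grids.

World coordinates follow the LPS scanner frame (+x subject-left, +y
subject-posterior, +z subject-superior).  Arrays are indexed ``[i, j, k]``
along (x, y, z); voxel ``(i, j, k)`` occupies the half-open world box
``[origin + idx*s, origin + (idx+1)*s)`` per axis, so its center sits at
``origin + (idx + 0.5) * s``.  This makes voxel-count <-> mm^3 conversion
exact and unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "Mask", "GridGeometryError"]


class GridGeometryError(ValueError):
    """Raised when grid shape/spacing/origin constraints are violated."""


def _as_triple(value, name: str) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size != 3 or not np.all(np.isfinite(arr)):
        raise GridGeometryError(f"{name} must be a finite length-3 vector, got {value!r}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class _Grid:
    """Shared geometry of :class:`Volume` and :class:`Mask`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GridGeometryError(f"expected a 3-D array, got shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing, "spacing")
        if min(self.spacing) <= 0:
            raise GridGeometryError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_geometry(self, other: "_Grid", *, tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def world_to_index(self, point) -> tuple[int, int, int]:
        """Index of the voxel whose half-open box contains ``point`` (world mm)."""
        p = _as_triple(point, "point")
        idx = []
        for ax in range(3):
            i = int(np.floor((p[ax] - self.origin[ax]) / self.spacing[ax]))
            if not 0 <= i < self.shape[ax]:
                raise GridGeometryError(
                    f"point {p} falls outside the grid on axis {ax} (index {i}, "
                    f"shape {self.shape})"
                )
            idx.append(i)
        return (idx[0], idx[1], idx[2])

    def index_to_world(self, index) -> tuple[float, float, float]:
        """World coordinates of the center of voxel ``index``."""
        i, j, k = index
        return (
            self.origin[0] + (i + 0.5) * self.spacing[0],
            self.origin[1] + (j + 0.5) * self.spacing[1],
            self.origin[2] + (k + 0.5) * self.spacing[2],
        )

    def world_bounds(self) -> tuple[tuple[float, float], ...]:
        """Per-axis (low, high) world extent of the grid box."""
        return tuple(
            (self.origin[ax], self.origin[ax] + self.shape[ax] * self.spacing[ax])
            for ax in range(3)
        )

    def contains_point(self, point) -> bool:
        p = _as_triple(point, "point")
        return all(lo <= p[ax] < hi for ax, (lo, hi) in enumerate(self.world_bounds()))


@dataclass
class Volume(_Grid):
    """A 3-D scalar image (CBCT grayscale) with voxel spacing in mm."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.dtype == bool:
            raise GridGeometryError("Volume intensities must be scalar, not boolean")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise GridGeometryError("Volume intensities must be finite everywhere")


@dataclass
class Mask(_Grid):
    """A boolean grid sharing a :class:`Volume`'s geometry."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        super().__post_init__()

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.data))

    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3
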