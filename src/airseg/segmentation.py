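"""Five-step nasal-airway segmentation.

1. smooth the grayscale volume (median, then Gaussian),
2. binarize at a threshold T (air = intensity <= T),
3. intersect with the landmark-defined ROI,
4. close sinus connections with geometric blocks,
5. region-grow from a seed and convert the voxel count to mm^3.

Also implements the connectivity-based threshold selection used in the
accuracy experiment: the highest threshold that keeps an inner air space
disconnected from the outer air.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import Mask, Volume
from .roi import LandmarkSet, build_roi_mask

__all__ = [
    "Block",
    "BlockSet",
    "SegParams",
    "SegmentationResult",
    "SegmentationError",
    "load_blocks",
    "save_blocks",
    "smooth_volume",
    "binarize_air",
    "apply_blocks",
    "region_grow",
    "measure_volume",
    "max_disconnecting_threshold",
    "segment_nasal_airway",
]


class SegmentationError(ValueError):
    """A pipeline stage failed (bad seed, empty result, no separating threshold)."""


_CONNECTIVITY_TO_STRUCT_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary structuring element for 6/18/26-connectivity."""
    if connectivity not in _CONNECTIVITY_TO_STRUCT_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_TO_STRUCT_RANK[connectivity])


@dataclass(frozen=True)
class Block:
    """A disk-slab that seals one sinus-airway connection.

    ``center`` (world mm) and unit ``normal`` define the mid-plane; the slab
    extends ``radius`` mm in-plane and ``thickness``/2 mm to each side along
    the normal.  Voxels whose centers fall inside are forced to tissue.
    """

    center: tuple[float, float, float]
    normal: tuple[float, float, float]
    radius: float
    thickness: float

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        if c.shape != (3,) or n.shape != (3,):
            raise ValueError("block center and normal must be 3-vectors")
        norm = float(np.linalg.norm(n))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"block normal must be unit length, |n| = {norm:.8f}")
        if self.radius <= 0:
            raise ValueError(f"block radius must be positive, got {self.radius}")
        if self.thickness <= 0:
            raise ValueError(f"block thickness must be positive, got {self.thickness}")
        object.__setattr__(self, "center", tuple(float(v) for v in c))
        object.__setattr__(self, "normal", tuple(float(v) for v in n))

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "normal": list(self.normal),
            "radius_mm": self.radius,
            "thickness_mm": self.thickness,
        }


BlockSet = tuple[Block, ...]


def load_blocks(path) -> BlockSet:
    """Load a JSON array of blocks ({center, normal, radius_mm, thickness_mm})."""
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, list):
        raise ValueError(f"{path}: blocks file must be a JSON array")
    return tuple(
        Block(
            center=tuple(entry["center"]),
            normal=tuple(entry["normal"]),
            radius=float(entry["radius_mm"]),
            thickness=float(entry["thickness_mm"]),
        )
        for entry in doc
    )


def save_blocks(blocks, path) -> None:
    Path(path).write_text(
        json.dumps([b.to_dict() for b in blocks], indent=2) + "\n"
    )


@dataclass(frozen=True)
class SegParams:
    """Segmentation parameters: threshold, smoothing, connectivity, seed."""

    threshold: float
    seed: tuple[float, float, float]
    median_radius: int = 1
    gaussian_sigma: float = 0.4
    connectivity: int = 6

    def __post_init__(self):
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.median_radius < 0 or int(self.median_radius) != self.median_radius:
            raise ValueError(f"median_radius must be a non-negative integer, got {self.median_radius}")
        if self.gaussian_sigma < 0:
            raise ValueError(f"gaussian_sigma must be >= 0, got {self.gaussian_sigma}")
        object.__setattr__(self, "seed", tuple(float(v) for v in self.seed))


@dataclass(frozen=True)
class SegmentationResult:
    mask: Mask
    voxel_count: int
    volume_mm3: float
    params: SegParams
    blocks: BlockSet
    landmarks: LandmarkSet | None = None

    def report(self) -> dict:
        """JSON-serializable provenance record."""
        blocks_doc = json.dumps([b.to_dict() for b in self.blocks], sort_keys=True)
        rep = {
            "voxel_count": self.voxel_count,
            "volume_mm3": self.volume_mm3,
            "threshold": self.params.threshold,
            "connectivity": self.params.connectivity,
            "median_radius": self.params.median_radius,
            "gaussian_sigma": self.params.gaussian_sigma,
            "seed": list(self.params.seed),
            "spacing": list(self.mask.spacing),
            "blocks_hash": hashlib.sha256(blocks_doc.encode()).hexdigest()[:16],
        }
        if self.landmarks is not None:
            lm_doc = json.dumps(
                {k: list(getattr(self.landmarks, k)) for k in
                 ("ba", "nasion", "ethmoid_pi", "septum_post_ant", "nares_post")},
                sort_keys=True,
            )
            rep["landmarks_hash"] = hashlib.sha256(lm_doc.encode()).hexdigest()[:16]
        return rep


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def smooth_volume(volume: Volume, median_radius: int = 1, gaussian_sigma: float = 0.4) -> Volume:
    """Median filter (cubic window, half-width in voxels) then Gaussian
    (physical sigma in mm, converted per axis).  Zero parameters are the
    identity; borders are edge-replicated.
    """
    if median_radius < 0 or int(median_radius) != median_radius:
        raise ValueError(f"median_radius must be a non-negative integer, got {median_radius}")
    if gaussian_sigma < 0:
        raise ValueError(f"gaussian_sigma must be >= 0, got {gaussian_sigma}")
    data = volume.data
    if median_radius > 0:
        data = ndimage.median_filter(data, size=2 * int(median_radius) + 1, mode="nearest")
    if gaussian_sigma > 0:
        sigmas = [gaussian_sigma / s for s in volume.spacing]
        data = ndimage.gaussian_filter(data.astype(np.float64), sigma=sigmas, mode="nearest")
    return Volume(np.ascontiguousarray(data), spacing=volume.spacing, origin=volume.origin)


def binarize_air(volume: Volume, threshold: float) -> Mask:
    """Air mask: true where intensity <= threshold (air is low-intensity)."""
    return Mask(volume.data <= threshold, spacing=volume.spacing, origin=volume.origin)


def _block_voxels(mask: Mask, block: Block) -> np.ndarray:
    """Boolean grid of voxel centers inside a block's disk-slab."""
    xc = mask.axis_centers(0)[:, None, None]
    yc = mask.axis_centers(1)[None, :, None]
    zc = mask.axis_centers(2)[None, None, :]
    cx, cy, cz = block.center
    nx, ny, nz = block.normal
    dx, dy, dz = xc - cx, yc - cy, zc - cz
    axial = dx * nx + dy * ny + dz * nz
    rad2 = (dx * dx + dy * dy + dz * dz) - axial * axial
    return (np.abs(axial) <= block.thickness / 2.0) & (rad2 <= block.radius**2)


def apply_blocks(mask: Mask, blocks) -> Mask:
    """Force voxels inside any block slab to tissue (false); warn on no-ops."""
    import warnings

    data = mask.data.copy()
    for block in blocks:
        inside = _block_voxels(mask, block)
        if not inside.any():
            warnings.warn(
                f"block at {block.center} lies entirely outside the grid; no effect",
                stacklevel=2,
            )
            continue
        data[inside] = False
    return Mask(data, spacing=mask.spacing, origin=mask.origin)


def region_grow(mask: Mask, seed, connectivity: int = 6) -> Mask:
    """The connected component of ``mask`` containing the world-mm ``seed``."""
    idx = mask.world_to_index(seed)
    if not mask.data[idx]:
        raise SegmentationError(
            f"seed {tuple(seed)} falls in a non-air voxel at index {idx}"
        )
    labels, _ = ndimage.label(mask.data, structure=connectivity_structure(connectivity))
    component = labels == labels[idx]
    return Mask(component, spacing=mask.spacing, origin=mask.origin)


def measure_volume(mask_or_count, spacing=None) -> tuple[float, float]:
    """(voxel_count, volume_mm3).  Accepts a Mask, or a (possibly fractional)
    count plus explicit spacing for the bare conversion utility."""
    if isinstance(mask_or_count, Mask):
        count = float(mask_or_count.voxel_count)
        sx, sy, sz = mask_or_count.spacing
    else:
        if spacing is None:
            raise ValueError("spacing required when passing a bare voxel count")
        count = float(mask_or_count)
        sx, sy, sz = spacing
    return count, count * sx * sy * sz


def _seeds_connected(air: np.ndarray, inner_idx, outer_idx, structure) -> bool:
    labels, _ = ndimage.label(air, structure=structure)
    return labels[inner_idx] == labels[outer_idx]


def max_disconnecting_threshold(
    volume: Volume, inner_seed, outer_seed, connectivity: int = 6
) -> float:
    """Largest threshold in the volume's discrete intensity set that keeps the
    inner and outer seeds in distinct air components.

    Disconnection is monotone: raising T only adds air voxels, which can only
    merge components — so a binary search over the sorted unique intensities
    is exact.
    """
    inner_idx = volume.world_to_index(inner_seed)
    outer_idx = volume.world_to_index(outer_seed)
    structure = connectivity_structure(connectivity)
    values = np.unique(volume.data)
    seed_min = max(volume.data[inner_idx], volume.data[outer_idx])
    lo = int(np.searchsorted(values, seed_min))  # first T making both seeds air
    if lo >= len(values):  # pragma: no cover - seeds always <= max by construction
        raise SegmentationError("seeds are not air voxels at any threshold")
    hi = len(values) - 1
    if _seeds_connected(volume.data <= values[lo], inner_idx, outer_idx, structure):
        raise SegmentationError(
            "no separating threshold: seeds are connected at every threshold "
            f"that keeps both air (first such threshold {values[lo]})"
        )
    # invariant: disconnected at values[lo], find last disconnected index
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _seeds_connected(volume.data <= values[mid], inner_idx, outer_idx, structure):
            hi = mid - 1
        else:
            lo = mid
    return float(values[lo])


def segment_nasal_airway(
    volume: Volume,
    landmarks: LandmarkSet | None,
    blocks,
    params: SegParams,
) -> SegmentationResult:
    """Run the full five-step pipeline and return the measured result."""
    blocks = tuple(blocks)
    smoothed = smooth_volume(volume, params.median_radius, params.gaussian_sigma)
    air = binarize_air(smoothed, params.threshold)
    if not air.data.any():
        raise SegmentationError(
            f"binarize_air emptied the mask: no intensity <= {params.threshold}"
        )
    if landmarks is not None:
        roi = build_roi_mask(volume, landmarks)
        air = Mask(air.data & roi.data, spacing=air.spacing, origin=air.origin)
        if not air.data.any():
            raise SegmentationError("ROI intersection emptied the air mask")
    if blocks:
        seed_idx = air.world_to_index(params.seed)
        blocked = apply_blocks(air, blocks)
        if air.data[seed_idx] and not blocked.data[seed_idx]:
            raise SegmentationError(
                f"seed {params.seed} lies inside a blocked voxel"
            )
        air = blocked
        if not air.data.any():
            raise SegmentationError("blocking emptied the air mask")
    try:
        grown = region_grow(air, params.seed, params.connectivity)
    except SegmentationError as exc:
        idx = smoothed.world_to_index(params.seed)
        raise SegmentationError(
            f"{exc} (smoothed intensity there: {smoothed.data[idx]})"
        ) from exc
    count, mm3 = measure_volume(grown)
    return SegmentationResult(
        mask=grown,
        voxel_count=int(count),
        volume_mm3=mm3,
        params=params,
        blocks=blocks,
        landmarks=landmarks,
    )
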