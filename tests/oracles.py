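"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (queues, per-voxel loops, direct
linear-system solves) and shares no code with the implementation paths it
validates.
"""

from collections import deque

import numpy as np


def neighbor_offsets(connectivity: int):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def bfs_flood_fill(data: np.ndarray, seed_idx, connectivity: int) -> np.ndarray:
    """Breadth-first flood fill of a boolean grid from one seed index."""
    assert data.dtype == bool and data[tuple(seed_idx)]
    offs = neighbor_offsets(connectivity)
    shape = data.shape
    out = np.zeros_like(data)
    out[tuple(seed_idx)] = True
    queue = deque([tuple(seed_idx)])
    while queue:
        i, j, k = queue.popleft()
        for dx, dy, dz in offs:
            a, b, c = i + dx, j + dy, k + dz
            if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= c < shape[2]:
                if data[a, b, c] and not out[a, b, c]:
                    out[a, b, c] = True
                    queue.append((a, b, c))
    return out


def seeds_connected(data: np.ndarray, idx_a, idx_b, connectivity: int) -> bool:
    if not (data[tuple(idx_a)] and data[tuple(idx_b)]):
        return False
    return bool(bfs_flood_fill(data, idx_a, connectivity)[tuple(idx_b)])


def exhaustive_disconnecting_threshold(volume, inner_idx, outer_idx, connectivity):
    """Scan every unique intensity from high to low for the largest threshold
    keeping the two seeds in distinct air components.  Returns None if no
    separating threshold exists."""
    values = np.unique(volume.data)
    seed_min = max(volume.data[tuple(inner_idx)], volume.data[tuple(outer_idx)])
    for t in values[::-1]:
        if t < seed_min:
            return None
        air = volume.data <= t
        if not seeds_connected(air, inner_idx, outer_idx, connectivity):
            return float(t)
    return None


def roi_predicate_mask(volume, y_anterior, y_posterior, z_sup) -> np.ndarray:
    """Per-voxel loop evaluation of the ROI membership predicate."""
    nx, ny, nz = volume.shape
    out = np.zeros(volume.shape, dtype=bool)
    for j in range(ny):
        y = volume.origin[1] + (j + 0.5) * volume.spacing[1]
        if not (y_anterior <= y <= y_posterior):
            continue
        roof = float(z_sup(y))
        for k in range(nz):
            z = volume.origin[2] + (k + 0.5) * volume.spacing[2]
            if z <= roof:
                out[:, j, k] = True
    return out


def natural_spline_eval(ys, zs, y):
    """Direct tridiagonal solve for a natural cubic spline through (ys, zs),
    evaluated at scalar y inside the knot span."""
    ys = np.asarray(ys, dtype=float)
    zs = np.asarray(zs, dtype=float)
    n = len(ys)
    h = np.diff(ys)
    # second derivatives M_i, natural: M_0 = M_{n-1} = 0
    a = np.zeros((n, n))
    rhs = np.zeros(n)
    a[0, 0] = 1.0
    a[-1, -1] = 1.0
    for i in range(1, n - 1):
        a[i, i - 1] = h[i - 1] / 6.0
        a[i, i] = (h[i - 1] + h[i]) / 3.0
        a[i, i + 1] = h[i] / 6.0
        rhs[i] = (zs[i + 1] - zs[i]) / h[i] - (zs[i] - zs[i - 1]) / h[i - 1]
    m = np.linalg.solve(a, rhs)
    i = int(np.clip(np.searchsorted(ys, y) - 1, 0, n - 2))
    t0, t1 = ys[i], ys[i + 1]
    hi = t1 - t0
    return (
        m[i] * (t1 - y) ** 3 / (6 * hi)
        + m[i + 1] * (y - t0) ** 3 / (6 * hi)
        + (zs[i] / hi - m[i] * hi / 6) * (t1 - y)
        + (zs[i + 1] / hi - m[i + 1] * hi / 6) * (y - t0)
    )


def slab_contains(block, point) -> bool:
    """Scalar point-in-disk-slab test."""
    p = np.asarray(point, dtype=float)
    c = np.asarray(block.center)
    n = np.asarray(block.normal)
    d = p - c
    axial = float(d @ n)
    radial2 = float(d @ d) - axial * axial
    return abs(axial) <= block.thickness / 2.0 and radial2 <= block.radius**2
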