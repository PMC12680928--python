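"""Marker-controlled watershed instancing on the intensity relief.

The flooding relief is the negated intensity -- brighter voxels flood first --
and the flooding domain is restricted to voxels with intensity >= tau, the
per-sample threshold. Each detected soma center seeds exactly one instance.

The flood is implemented explicitly as a best-first priority queue so that its
behaviour is fully pinned down: equal-priority voxels are popped in FIFO
insertion order, and markers are seeded in lexicographic (z, y, x) order of
their voxel coordinates. This makes the output deterministic and directly
comparable, voxel for voxel, with an independent brute-force flood.
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np

from .errors import ConfigurationError
from .detect import DetectionSet
from .grid import LabelVolume, VoxelGrid

__all__ = [
    "watershed_instances",
    "exclude_edge_instances",
    "relabel_consecutive",
    "neighbor_offsets",
]


def neighbor_offsets(connectivity: int = 26) -> np.ndarray:
    """Voxel neighbor offsets for 6- or 26-connectivity, lexicographic order."""
    if connectivity == 6:
        return np.array(
            [(-1, 0, 0), (0, -1, 0), (0, 0, -1), (0, 0, 1), (0, 1, 0), (1, 0, 0)]
        )
    if connectivity == 26:
        offs = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
        return np.array(offs)
    raise ConfigurationError("connectivity must be 6 or 26")


def _snap_marker(idx, domain, max_radius=3):
    """Snap a marker on a sub-tau voxel to the nearest in-domain voxel within
    ``max_radius`` voxels (Euclidean in index space); None if impossible."""
    if domain[tuple(idx)]:
        return tuple(idx)
    shape = domain.shape
    best, best_d = None, np.inf
    r = max_radius
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                z, y, x = idx[0] + dz, idx[1] + dy, idx[2] + dx
                if not (0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
                    continue
                if not domain[z, y, x]:
                    continue
                d = dz * dz + dy * dy + dx * dx
                if d < best_d:
                    best, best_d = (z, y, x), d
    return best


def watershed_instances(
    grid: VoxelGrid,
    markers: DetectionSet,
    tau: float,
    connectivity: int = 26,
) -> LabelVolume:
    """Flood the intensity relief from soma markers, restricted to >= tau.

    Each marker seeds one label (1..K in the order markers are given); voxels
    below tau stay background. Markers on sub-tau voxels are snapped to the
    nearest in-domain voxel within 3 voxels, else dropped with a warning.
    """
    data = grid.data
    labels = np.zeros(data.shape, dtype=np.int32)
    if len(markers) == 0:
        return LabelVolume(labels, grid.spacing)
    if not (data.min() <= tau <= data.max()):
        raise ConfigurationError(
            f"tau={tau} lies outside the intensity range [{data.min()}, {data.max()}]"
        )

    domain = data >= tau
    offs = neighbor_offsets(connectivity)

    seeds = []
    for k, c in enumerate(markers.centers_um, start=1):
        idx = np.rint((np.asarray(c) - np.array(grid.origin)) / np.array(grid.spacing)).astype(int)
        idx = np.clip(idx, 0, np.array(data.shape) - 1)
        snapped = _snap_marker(idx, domain)
        if snapped is None:
            warnings.warn(f"marker {k} at {tuple(idx)} has no >= tau voxel within 3; dropped")
            continue
        seeds.append((snapped, k))

    # lexicographic seeding order; FIFO tie-break via a monotone counter
    heap: list[tuple[float, int, int, int, int, int]] = []
    counter = 0
    for (z, y, x), k in sorted(seeds):
        if labels[z, y, x] != 0:
            continue  # two markers snapped onto the same voxel: first wins
        labels[z, y, x] = k
        heapq.heappush(heap, (-float(data[z, y, x]), counter, z, y, x, k))
        counter += 1

    shape = data.shape
    while heap:
        _, _, z, y, x, k = heapq.heappop(heap)
        for dz, dy, dx in offs:
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]):
                continue
            if labels[nz, ny, nx] != 0 or not domain[nz, ny, nx]:
                continue
            labels[nz, ny, nx] = k
            heapq.heappush(heap, (-float(data[nz, ny, nx]), counter, nz, ny, nx, k))
            counter += 1

    return LabelVolume(labels, grid.spacing)


def _normalize_margin(margin, shape) -> tuple[int, int, int]:
    if np.isscalar(margin):
        margin = (int(margin),) * 3
    margin = tuple(int(m) for m in margin)
    if any(m < 0 for m in margin):
        raise ConfigurationError("margin must be >= 0")
    if max(margin) >= min(shape) / 2:
        raise ConfigurationError(
            f"margin {margin} is >= half the smallest grid dimension {min(shape)}"
        )
    return margin


def exclude_edge_instances(labels: LabelVolume, margin) -> tuple[LabelVolume, list[int]]:
    """Remove instances whose bounding box intersects the outer margin shell.

    ``margin`` is a voxel count, scalar or per-axis ``(mz, my, mx)``; a margin
    of 0 along an axis disables the rule for that axis (face-touching allowed,
    as for the axial truncation of physical sections). Returns the filtered
    volume and the excluded ids.
    """
    from scipy.ndimage import find_objects

    m = _normalize_margin(margin, labels.shape)
    out = labels.labels.copy()
    excluded: list[int] = []
    for i, sl in enumerate(find_objects(labels.labels), start=1):
        if sl is None:
            continue
        bbox = tuple((s.start, s.stop) for s in sl)
        hits = any(
            mm > 0 and (start < mm or stop > size - mm)
            for (start, stop), size, mm in zip(bbox, labels.shape, m)
        )
        if hits:
            out[out == i] = 0
            excluded.append(i)
    return LabelVolume(out, labels.spacing), excluded


def relabel_consecutive(labels: LabelVolume) -> LabelVolume:
    """Remap positive labels to 1..K in order of first appearance (raster
    scan); background is preserved."""
    flat = labels.labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    order = uniq[np.argsort(first)]
    order = order[order > 0]
    mapping = np.zeros(int(labels.labels.max()) + 1 if labels.labels.size else 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        mapping[old] = new
    return LabelVolume(mapping[labels.labels] if labels.labels.size else labels.labels.copy(),
                       labels.spacing)
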