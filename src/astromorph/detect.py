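"""Soma detection: one seed point per astrocyte for the watershed stage.

The classical backend computes an anisotropy-aware Euclidean distance
transform of the foreground mask, smooths it, and takes local maxima with a
minimum physical separation. Somata are the thickest structures in an
astrocyte, so distance peaks sit at soma centers; branch junctions produce
much shallower peaks. Confidence is the peak value normalized by the sample's
maximum peak, making the 0.8 confidence cutoff meaningful across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, find_objects, gaussian_filter
from skimage.feature import peak_local_max

from .errors import ConfigurationError
from .grid import LabelVolume, VoxelGrid
from .semantic import ForegroundResult

__all__ = ["DetectionSet", "detect_somata", "boxes_from_labels"]


@dataclass
class DetectionSet:
    """Candidate soma centers with confidences (sorted descending)."""

    centers_um: np.ndarray  # (N, 3) physical coordinates
    confidences: np.ndarray  # (N,) in [0, 1]
    boxes: list | None = None  # optional half-open voxel boxes

    def __post_init__(self):
        self.centers_um = np.asarray(self.centers_um, dtype=float).reshape(-1, 3)
        self.confidences = np.asarray(self.confidences, dtype=float).reshape(-1)
        if len(self.centers_um) != len(self.confidences):
            raise ConfigurationError("centers and confidences lengths differ")
        if self.boxes is not None and len(self.boxes) != len(self.centers_um):
            raise ConfigurationError("boxes length differs from centers")
        if self.confidences.size and (
            self.confidences.min() < 0 or self.confidences.max() > 1
        ):
            raise ConfigurationError("confidences must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.centers_um)

    @classmethod
    def empty(cls) -> "DetectionSet":
        return cls(np.empty((0, 3)), np.empty(0))

    def filtered(self, confidence_threshold: float) -> "DetectionSet":
        keep = self.confidences >= confidence_threshold
        boxes = [b for b, k in zip(self.boxes, keep) if k] if self.boxes else None
        return DetectionSet(self.centers_um[keep], self.confidences[keep], boxes)


def detect_somata(
    grid: VoxelGrid,
    fg: ForegroundResult,
    backend: str = "classical",
    confidence_threshold: float = 0.8,
    min_separation_um: float = 16.0,
    smoothing_sigma_um: float = 1.0,
) -> DetectionSet:
    """Detect soma centers inside the foreground mask.

    Only detections with confidence >= ``confidence_threshold`` (default 0.8,
    chosen to suppress false positives) are returned, sorted by descending
    confidence.
    """
    if not (0.0 <= confidence_threshold <= 1.0):
        raise ConfigurationError("confidence_threshold must lie in [0, 1]")
    if backend == "learned":
        raise ConfigurationError(
            "learned backend requires a trained model artifact and the optional "
            "torch dependency; use backend='classical'"
        )
    if backend != "classical":
        raise ConfigurationError(f"unknown backend {backend!r}")

    mask = fg.mask
    if not mask.any():
        return DetectionSet.empty()

    spacing = np.array(grid.spacing)
    edt = distance_transform_edt(mask, sampling=spacing)
    if smoothing_sigma_um > 0:
        edt = gaussian_filter(edt, sigma=smoothing_sigma_um / spacing)

    # anisotropic non-maximum suppression footprint from the physical separation
    half = np.maximum(1, np.floor(min_separation_um / spacing).astype(int))
    footprint = np.ones(2 * half + 1, dtype=bool)
    peaks = peak_local_max(edt, footprint=footprint, labels=mask, exclude_border=False)
    if len(peaks) == 0:
        return DetectionSet.empty()

    values = edt[tuple(peaks.T)]
    conf = values / values.max()
    order = np.lexsort((peaks[:, 2], peaks[:, 1], peaks[:, 0], -conf))
    peaks, conf = peaks[order], conf[order]
    keep = conf >= confidence_threshold
    centers = peaks[keep] * spacing + np.array(grid.origin)
    return DetectionSet(centers, conf[keep])


def boxes_from_labels(labels: LabelVolume, pad: int = 0) -> dict[int, tuple]:
    """Tight half-open bounding box per positive label, dilated by ``pad``
    voxels and clipped to the grid. Returns ``{label: ((z0,z1),(y0,y1),(x0,x1))}``."""
    if pad < 0:
        raise ConfigurationError("pad must be >= 0")
    out: dict[int, tuple] = {}
    slices = find_objects(labels.labels)
    for i, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        box = tuple(
            (max(0, s.start - pad), min(size, s.stop + pad))
            for s, size in zip(sl, labels.shape)
        )
        out[i] = box
    return out
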