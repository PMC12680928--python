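"""Semantic foreground/background separation and the per-sample threshold.

The downstream instancing stage needs two things from this module: a binary
foreground mask and a per-sample intensity threshold tau -- the lowest
intensity a watershed instance may include. The classical backend smooths the
stack with an anisotropy-aware Gaussian, applies Otsu's global threshold, and
converts the exceedance into a pseudo-probability so that the ``prob >= 0.5``
contract is backend-independent. tau is a low percentile (default q = 1) of
the raw intensities inside the mask: close to the dimmest genuine cell signal
but robust to noise outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, NoForegroundError, UndefinedThresholdError
from .grid import VoxelGrid

__all__ = [
    "ForegroundResult",
    "segment_foreground",
    "derive_sample_threshold",
    "threshold_statistics",
]


@dataclass
class ForegroundResult:
    """Foreground probability map, binary mask and per-sample threshold."""

    prob: np.ndarray
    mask: np.ndarray
    sample_threshold: float | None  # None when undefined (empty/full mask)

    def __post_init__(self):
        if self.prob.min() < 0 or self.prob.max() > 1:
            raise ConfigurationError("prob must lie in [0, 1]")
        if not np.array_equal(self.mask, self.prob >= 0.5):
            raise ConfigurationError("mask must equal (prob >= 0.5)")


def segment_foreground(
    grid: VoxelGrid,
    backend: str = "classical",
    smoothing_sigma_um: float = 0.4,
    global_threshold: float | None = None,
    q: float = 1.0,
) -> ForegroundResult:
    """Separate astrocyte foreground from background.

    Parameters
    ----------
    grid
        Input intensity stack.
    backend
        ``"classical"`` (Gaussian smoothing + Otsu + logistic pseudo-
        probability). ``"learned"`` requires the optional torch dependency and
        is not available in this build.
    smoothing_sigma_um
        Physical smoothing scale; converted per-axis by the voxel spacing.
    global_threshold
        Override for the global intensity threshold (default: Otsu on the
        smoothed stack).
    q
        Percentile (0-100) of in-mask raw intensities defining tau.
    """
    if backend == "learned":
        raise ConfigurationError(
            "learned backend requires a trained model artifact and the optional "
            "torch dependency; use backend='classical'"
        )
    if backend != "classical":
        raise ConfigurationError(f"unknown backend {backend!r}")

    data = grid.data.astype(np.float64)
    if data.max() == data.min():
        raise NoForegroundError("no foreground separable: image is constant")

    sigma_vox = smoothing_sigma_um / np.array(grid.spacing)
    smoothed = gaussian_filter(data, sigma=sigma_vox) if smoothing_sigma_um > 0 else data

    thr = float(threshold_otsu(smoothed)) if global_threshold is None else float(global_threshold)

    # Logistic squashing of (intensity - threshold) / noise-scale; the noise
    # scale is the robust SD of the high-frequency residual.
    resid = data - smoothed
    scale = float(np.median(np.abs(resid - np.median(resid))) * 1.4826)
    scale = max(scale, 1e-9)
    prob = expit((smoothed - thr) / scale)
    mask = prob >= 0.5

    try:
        tau = derive_sample_threshold(grid, prob, q=q)
    except UndefinedThresholdError:
        tau = None
    return ForegroundResult(prob=prob, mask=mask, sample_threshold=tau)


def derive_sample_threshold(grid: VoxelGrid, prob: np.ndarray, q: float = 1.0) -> float:
    """Per-sample threshold tau between background and cells.

    tau is the q-th percentile (default q = 1) of raw intensities over voxels
    with ``prob >= 0.5``. Raises :class:`UndefinedThresholdError` when the
    foreground or the background is empty.
    """
    if prob.shape != grid.data.shape:
        raise ConfigurationError("prob and grid shapes differ")
    fg = prob >= 0.5
    n_fg = int(fg.sum())
    if n_fg == 0 or n_fg == prob.size:
        raise UndefinedThresholdError(
            "undefined threshold: need at least one foreground and one background voxel"
        )
    return float(np.percentile(grid.data[fg], q))


def threshold_statistics(taus) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of a collection of per-sample thresholds."""
    taus = np.asarray(list(taus), dtype=float)
    if taus.size == 0:
        raise ConfigurationError("no thresholds given")
    sd = float(np.std(taus, ddof=1)) if taus.size > 1 else 0.0
    return float(np.mean(taus)), sd
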