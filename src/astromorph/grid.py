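"""Core volumetric containers: intensity grids and instance label volumes.

Conventions used throughout the package:

* voxel indices are 0-based in ``(z, y, x)`` order;
* the physical coordinate of a voxel is ``origin + index * spacing``
  (voxel-center convention), with spacing in micrometres per voxel;
* bounding boxes are half-open in voxel indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigurationError

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "acquisition_geometry",
    "save_grid",
    "load_grid",
    "save_labels",
    "load_labels",
]


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ConfigurationError(f"spacing must be 3 positive floats, got {spacing}")
    return spacing


@dataclass
class VoxelGrid:
    """A 3D fluorescence intensity stack with anisotropic voxel spacing.

    Parameters
    ----------
    data
        3D non-negative intensity array, axes ``(z, y, x)``.
    spacing
        ``(dz, dy, dx)`` voxel size in micrometres.
    origin
        Physical coordinate (um) of voxel ``(0, 0, 0)``.
    metadata
        Free-form acquisition record (seed, sample id, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or any(s < 1 for s in self.data.shape):
            raise ConfigurationError(
                f"intensity data must be 3D with each axis >= 1, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ConfigurationError("intensities must be finite and non-negative")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis (um)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def index_to_um(self, idx) -> np.ndarray:
        """Physical coordinates (um) of voxel indices (voxel-center convention)."""
        return np.asarray(idx, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def um_to_index(self, coords) -> np.ndarray:
        """Nearest voxel index for physical coordinates in um."""
        rel = (np.asarray(coords, dtype=float) - np.array(self.origin)) / np.array(self.spacing)
        return np.rint(rel).astype(int)


@dataclass
class LabelVolume:
    """Integer instance labels on a voxel grid; 0 is background."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ConfigurationError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ConfigurationError("labels must be integer-typed")
        if self.labels.size and self.labels.min() < 0:
            raise ConfigurationError("labels must be >= 0")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def ids(self) -> np.ndarray:
        """Sorted positive instance ids present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]

    def voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))


def acquisition_geometry(
    n_slices: int = 30,
    z_step_um: float = 0.93,
    field_um: float = 143.0,
    n_px: int = 512,
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Grid shape and spacing emulating a confocal astrocyte acquisition.

    The default mirrors a 63x z-stack: ~30 slices spanning ~28 um axially and a
    square 143 um lateral field; ``n_px`` lateral pixels give the lateral
    spacing ``field_um / n_px`` (~0.28 um at 512 px).

    Returns ``(shape, spacing)`` with shape ``(n_slices, n_px, n_px)`` and
    spacing ``(z_step_um, d, d)``.
    """
    if n_slices < 1 or n_px < 1 or z_step_um <= 0 or field_um <= 0:
        raise ConfigurationError("acquisition geometry parameters must be positive")
    d = field_um / n_px
    return (n_slices, n_px, n_px), (z_step_um, d, d)


# ---------------------------------------------------------------------------
# On-disk formats: multi-page TIFF + JSON sidecar. Voxel spacing always comes
# from the sidecar (TIFF resolution tags are not trusted); a missing sidecar is
# a hard error.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_grid(grid: VoxelGrid, path) -> None:
    path = Path(path)
    data = grid.data
    if np.issubdtype(data.dtype, np.floating):
        data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {"spacing_um": list(grid.spacing), "origin_um": list(grid.origin)}
    sidecar.update({k: v for k, v in grid.metadata.items() if _json_safe(v)})
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_grid(path) -> VoxelGrid:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise ConfigurationError(
            f"missing JSON sidecar {sidecar_file}; voxel spacing must be supplied "
            "explicitly and is never guessed from TIFF tags"
        )
    sidecar = json.loads(sidecar_file.read_text())
    data = tifffile.imread(path).astype(np.float64)
    meta = {k: v for k, v in sidecar.items() if k not in ("spacing_um", "origin_um")}
    return VoxelGrid(
        data,
        tuple(sidecar["spacing_um"]),
        tuple(sidecar.get("origin_um", (0.0, 0.0, 0.0))),
        meta,
    )


def save_labels(vol: LabelVolume, path) -> None:
    path = Path(path)
    if vol.labels.size and vol.labels.max() > np.iinfo(np.uint16).max:
        raise ConfigurationError("label ids exceed uint16 range")
    tifffile.imwrite(path, vol.labels.astype(np.uint16))
    _sidecar_path(path).write_text(
        json.dumps({"spacing_um": list(vol.spacing)}, indent=2, sort_keys=True)
    )


def load_labels(path) -> LabelVolume:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise ConfigurationError(f"missing JSON sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    return LabelVolume(tifffile.imread(path).astype(np.int32), tuple(sidecar["spacing_um"]))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
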