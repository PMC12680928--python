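"""Synthetic astrocyte volume generator with exact ground truth.

Astrocytes in cortical confocal stacks appear as sparse, bright, star-shaped
cells: a roughly spherical soma with several tapering, tortuous processes,
truncated axially by the section thickness. This module samples such cells as
skeleton trees, rasterizes them onto an anisotropic voxel grid (producing
ground-truth instance labels, voxel-count volumes and marching-cubes surface
areas), renders a noisy blurred intensity stack, and writes multi-sample
benchmarks with a train/test split so every downstream stage can be scored
against known truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import find_objects, gaussian_filter

from .errors import ConfigurationError, PlacementInfeasibleError
from .grid import LabelVolume, VoxelGrid, acquisition_geometry, save_grid, save_labels

__all__ = [
    "SkeletonTree",
    "GroundTruthCell",
    "SimulationConfig",
    "sample_cells",
    "sample_tree",
    "rasterize",
    "render",
    "make_benchmark",
    "analytic_tree_volume",
    "analytic_tree_area",
    "sample_morphometry_table",
]

GT_CSV_HEADER = "cell_id,cz_um,cy_um,cx_um,volume_um3,area_um2,touches_edge"


@dataclass
class SkeletonTree:
    """Ground-truth morphology of one simulated cell.

    ``nodes`` are physical (z, y, x) coordinates in um; node 0 is the soma
    center and ``parents[0] == -1``. ``radii`` give the local process radius at
    each node and are non-increasing from root to tip along every path (taper).
    """

    nodes: np.ndarray
    parents: np.ndarray
    radii: np.ndarray
    soma_center: np.ndarray
    soma_radius: float

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.parents = np.asarray(self.parents, dtype=int)
        self.radii = np.asarray(self.radii, dtype=float)
        self.soma_center = np.asarray(self.soma_center, dtype=float)
        if self.parents[0] != -1:
            raise ConfigurationError("node 0 must be the root (parent -1)")
        if np.any(self.radii <= 0) or self.soma_radius <= 0:
            raise ConfigurationError("radii must be positive")

    def edges(self) -> list[tuple[int, int]]:
        return [(int(p), i) for i, p in enumerate(self.parents) if p >= 0]

    def edge_segments_um(self) -> np.ndarray:
        """(M, 2, 3) array of physical segment endpoints, parent first."""
        e = self.edges()
        if not e:
            return np.empty((0, 2, 3))
        return np.stack([np.stack([self.nodes[p], self.nodes[c]]) for p, c in e])


@dataclass
class GroundTruthCell:
    cell_id: int
    skeleton: SkeletonTree
    true_volume: float  # um^3, voxel count x voxel volume
    true_surface_area: float  # um^2, marching-cubes mesh area
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open
    touches_edge: bool
    soma_center_um: np.ndarray = None


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    The default geometry follows the acquisition this generator emulates
    (~30 z-slices of 0.93 um spanning a 143 um square field); the lateral
    sampling defaults to 240 px (0.596 um) as the package's desk-scale default,
    with the full 512 px sampling reachable through ``lateral_px``.
    """

    n_slices: int = 30
    z_step_um: float = 0.93
    field_um: float = 143.0
    lateral_px: int = 240

    n_cells: int = 5
    min_separation_um: float = 32.0
    placement_margin_um: float = 32.0
    z_jitter_um: float = 3.0
    soma_radius_um: tuple[float, float] = (5.0, 5.6)

    n_branches: int = 6
    branch_jitter: int = 1
    branch_length_um: tuple[float, float] = (14.0, 22.0)
    segment_length_um: float = 3.0
    tortuosity: float = 0.15  # direction jitter (rad-scale) per segment step
    root_radius_um: float = 1.6
    tip_radius_um: float = 0.9
    bifurcation_prob: float = 0.4
    process_radius_scale: float = 1.0  # swelling dial: 1.2 scales process radii

    background: float = 100.0
    amplitude: float = 400.0
    psf_sigma_um: tuple[float, float, float] = (0.8, 0.4, 0.4)
    noise_model: str = "gaussian"  # or "poisson"
    noise_sd: float = 8.0

    edge_margin_voxels: tuple[int, int, int] = (0, 1, 1)  # (z, y, x)
    n_samples: int = 7
    n_train: int = 5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.soma_radius_um
        if not (0 < lo <= hi):
            raise ConfigurationError("soma radius range must be positive and ordered")
        if self.min_separation_um < 2 * hi:
            raise ConfigurationError(
                "minimum soma separation must be >= 2x the maximum soma radius"
            )
        if self.branch_length_um[0] > self.branch_length_um[1]:
            raise ConfigurationError("branch length range must be ordered")
        if self.tip_radius_um > self.root_radius_um:
            raise ConfigurationError("process taper requires tip radius <= root radius")
        if self.background < 0 or self.amplitude < 0:
            raise ConfigurationError("background and amplitude must be non-negative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        if self.n_cells < 0 or self.n_samples < 1:
            raise ConfigurationError("n_cells must be >= 0 and n_samples >= 1")

    @property
    def geometry(self):
        return acquisition_geometry(self.n_slices, self.z_step_um, self.field_um, self.lateral_px)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.geometry[0]

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.geometry[1]

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Cell sampling
# ---------------------------------------------------------------------------


def _unit_vector(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _grow_chain(nodes, parents, radii, start_idx, direction, length, r_start, cfg, rng):
    """Append a tortuous chain of segments; returns (node indices, end radius)."""
    n_seg = max(1, int(np.ceil(length / cfg.segment_length_um)))
    tip_r = min(cfg.tip_radius_um * cfg.process_radius_scale, r_start)
    idx = start_idx
    chain = []
    d = np.array(direction, dtype=float)
    for k in range(1, n_seg + 1):
        d = d + cfg.tortuosity * rng.normal(size=3)
        d /= np.linalg.norm(d)
        r = r_start + (tip_r - r_start) * (k / n_seg)
        r = min(r, radii[idx])  # taper invariant along the path
        new = nodes[idx] + d * (length / n_seg)
        nodes.append(new)
        parents.append(idx)
        radii.append(r)
        idx = len(nodes) - 1
        chain.append(idx)
    return chain, radii[idx]


def sample_tree(cfg: SimulationConfig, center, rng) -> SkeletonTree:
    """Sample one astrocyte-like skeleton rooted at ``center`` (um)."""
    center = np.asarray(center, dtype=float)
    soma_r = rng.uniform(*cfg.soma_radius_um)
    nodes = [center.copy()]
    parents = [-1]
    radii = [cfg.root_radius_um * cfg.process_radius_scale]

    n_br = cfg.n_branches
    if cfg.branch_jitter:
        n_br = int(n_br + rng.integers(-cfg.branch_jitter, cfg.branch_jitter + 1))
    n_br = max(0, n_br)

    root_r = cfg.root_radius_um * cfg.process_radius_scale
    for _ in range(n_br):
        d = _unit_vector(rng)
        length = rng.uniform(*cfg.branch_length_um)
        # branch starts at the soma surface
        surf = center + d * soma_r
        nodes.append(surf)
        parents.append(0)
        radii.append(root_r)
        start = len(nodes) - 1
        chain, end_r = _grow_chain(nodes, parents, radii, start, d, length, root_r, cfg, rng)
        if cfg.bifurcation_prob > 0 and rng.random() < cfg.bifurcation_prob and len(chain) >= 2:
            pivot = chain[rng.integers(len(chain) // 3, max(len(chain) // 3 + 1, 2 * len(chain) // 3))]
            d2 = _unit_vector(rng)
            parent_dir = nodes[pivot] - nodes[parents[pivot]]
            parent_dir /= np.linalg.norm(parent_dir)
            d2 = d2 - (d2 @ parent_dir) * parent_dir  # roughly orthogonal offshoot
            d2 = 0.6 * parent_dir + 0.8 * d2 / max(np.linalg.norm(d2), 1e-9)
            d2 /= np.linalg.norm(d2)
            _grow_chain(
                nodes, parents, radii, pivot, d2, 0.6 * length, radii[pivot], cfg, rng
            )

    return SkeletonTree(np.array(nodes), np.array(parents), np.array(radii), center, soma_r)


def _place_somata(cfg: SimulationConfig, rng, max_restarts=80, max_tries=400) -> np.ndarray:
    if cfg.n_cells == 0:
        return np.empty((0, 3))
    (nz, ny, nx), (dz, dy, dx) = cfg.geometry
    ext = np.array([nz * dz, ny * dy, nx * dx])
    m = cfg.placement_margin_um
    lo = np.array([ext[0] / 2 - cfg.z_jitter_um, m, m])
    hi = np.array([ext[0] / 2 + cfg.z_jitter_um, ext[1] - m, ext[2] - m])
    if np.any(hi <= lo):
        raise ConfigurationError("placement margin leaves no room for somata")
    for _ in range(max_restarts):
        pts: list[np.ndarray] = []
        for _cell in range(cfg.n_cells):
            for _try in range(max_tries):
                p = rng.uniform(lo, hi)
                if all(np.linalg.norm(p - q) >= cfg.min_separation_um for q in pts):
                    pts.append(p)
                    break
            else:
                break
        if len(pts) == cfg.n_cells:
            return np.array(pts)
    raise PlacementInfeasibleError(
        f"could not place {cfg.n_cells} somata with separation "
        f">= {cfg.min_separation_um} um (placement infeasible)"
    )


def sample_cells(cfg: SimulationConfig, rng_seed: int) -> list[SkeletonTree]:
    """Sample ``cfg.n_cells`` skeleton trees with pairwise-separated somata."""
    rng = np.random.default_rng(rng_seed)
    centers = _place_somata(cfg, rng)
    return [sample_tree(cfg, c, rng) for c in centers]


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _local_box(lo_um, hi_um, shape, spacing):
    """Half-open voxel box covering the physical box [lo_um, hi_um]."""
    lo = np.floor(np.asarray(lo_um) / np.asarray(spacing)).astype(int)
    hi = np.ceil(np.asarray(hi_um) / np.asarray(spacing)).astype(int) + 1
    lo = np.clip(lo, 0, shape)
    hi = np.clip(hi, 0, shape)
    return lo, hi


def _box_coords(lo, hi, spacing):
    axes = [np.arange(lo[a], hi[a]) * spacing[a] for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _paint_sphere(labels, best, cell_id, center, radius, shape, spacing):
    lo, hi = _local_box(center - radius, center + radius, shape, spacing)
    if np.any(lo >= hi):
        return
    zz, yy, xx = _box_coords(lo, hi, spacing)
    d = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    region = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    inside = d <= radius
    win = inside & (d < best[region])
    best[region][win] = d[win]
    labels[region][win] = cell_id


def _paint_segment(labels, best, cell_id, p0, p1, r0, r1, shape, spacing):
    rmax = max(r0, r1)
    lo_um = np.minimum(p0, p1) - rmax
    hi_um = np.maximum(p0, p1) + rmax
    lo, hi = _local_box(lo_um, hi_um, shape, spacing)
    if np.any(lo >= hi):
        return
    zz, yy, xx = _box_coords(lo, hi, spacing)
    p = np.stack([zz, yy, xx], axis=-1)
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0:
        _paint_sphere(labels, best, cell_id, p0, rmax, shape, spacing)
        return
    t = np.clip(((p - p0) @ v) / vv, 0.0, 1.0)
    closest = p0 + t[..., None] * v
    d = np.linalg.norm(p - closest, axis=-1)
    r = r0 + (r1 - r0) * t
    region = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    win = (d <= r) & (d < best[region])
    best[region][win] = d[win]
    labels[region][win] = cell_id


def _mesh_area(mask: np.ndarray, spacing) -> float:
    # local import: morphometry also uses this oracle; keep one definition
    from .morphometry import mask_surface_area

    return mask_surface_area(mask, spacing)


def _touches(bbox, shape, margin) -> bool:
    for (start, stop), size, m in zip(bbox, shape, margin):
        if m > 0 and (start < m or stop > size - m):
            return True
    return False


def rasterize(
    trees: list[SkeletonTree],
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    edge_margin_voxels=(0, 1, 1),
) -> tuple[LabelVolume, list[GroundTruthCell]]:
    """Rasterize skeleton trees into an instance label volume with ground truth.

    A voxel center belongs to cell k if it lies within the soma sphere or
    within the local process radius of any edge of cell k; voxels claimed by
    several cells go to the nearest centerline (ties to the lower cell id,
    enforced by painting cells in id order with strict improvement).
    """
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf, dtype=np.float32)
    for cid, tree in enumerate(trees, start=1):
        _paint_sphere(labels, best, cid, tree.soma_center, tree.soma_radius, shape, spacing)
        for pidx, cidx in tree.edges():
            _paint_segment(
                labels, best, cid,
                tree.nodes[pidx], tree.nodes[cidx],
                tree.radii[pidx], tree.radii[cidx],
                shape, spacing,
            )

    vox_vol = float(np.prod(spacing))
    cells: list[GroundTruthCell] = []
    slices = find_objects(labels)
    for cid, tree in enumerate(trees, start=1):
        sl = slices[cid - 1] if cid - 1 < len(slices) else None
        if sl is None:
            warnings.warn(f"cell {cid} rasterized to zero voxels; omitted from ground truth")
            continue
        bbox = tuple((s.start, s.stop) for s in sl)
        mask = labels[sl] == cid
        n_vox = int(mask.sum())
        cells.append(
            GroundTruthCell(
                cell_id=cid,
                skeleton=tree,
                true_volume=n_vox * vox_vol,
                true_surface_area=_mesh_area(mask, spacing),
                bbox=bbox,
                touches_edge=_touches(bbox, shape, edge_margin_voxels),
                soma_center_um=tree.soma_center.copy(),
            )
        )
    return LabelVolume(labels, tuple(spacing)), cells


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render(labels: LabelVolume, cfg: SimulationConfig, rng_seed: int) -> VoxelGrid:
    """Render an intensity stack: background + amplitude on the foreground,
    Gaussian PSF blur (anisotropy-aware), then Gaussian or Poisson noise."""
    if cfg.background < 0 or cfg.amplitude < 0:
        raise ConfigurationError("background and amplitude must be non-negative")
    rng = np.random.default_rng(rng_seed)
    img = cfg.background + cfg.amplitude * (labels.labels > 0).astype(np.float64)
    sigma_vox = np.array(cfg.psf_sigma_um) / np.array(labels.spacing)
    if np.any(sigma_vox > 0):
        img = gaussian_filter(img, sigma=sigma_vox)
    if cfg.noise_model == "gaussian":
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    else:  # poisson
        img = rng.poisson(np.maximum(img, 0)).astype(np.float64)
    img = np.maximum(img, 0.0)
    return VoxelGrid(img, labels.spacing, metadata={"seed": int(rng_seed)})


# ---------------------------------------------------------------------------
# Benchmark writer
# ---------------------------------------------------------------------------


def _sample_seed(base_seed: int, i: int) -> int:
    return int((base_seed * 100003 + 7919 * i + 1) % (2**31))


def simulate_sample(cfg: SimulationConfig, seed: int):
    """Generate one sample: (VoxelGrid, LabelVolume, ground-truth cells)."""
    trees = sample_cells(cfg, seed)
    lab, cells = rasterize(trees, cfg.shape, cfg.spacing, cfg.edge_margin_voxels)
    grid = render(lab, cfg, seed + 1)
    return grid, lab, cells


def ground_truth_csv(cells: list[GroundTruthCell]) -> str:
    lines = [GT_CSV_HEADER]
    for c in cells:
        cz, cy, cx = c.soma_center_um
        lines.append(
            f"{c.cell_id},{cz:.4f},{cy:.4f},{cx:.4f},"
            f"{c.true_volume:.6f},{c.true_surface_area:.6f},{int(c.touches_edge)}"
        )
    return "\n".join(lines) + "\n"


def make_benchmark(cfg: SimulationConfig, out_dir, seed: int | None = None) -> dict:
    """Write a multi-sample benchmark (image/label TIFFs, ground-truth CSVs)
    and return its manifest (also written as ``manifest.json``).

    Split assignment: the first ``n_train`` samples are "train", the rest
    "test"; a single-sample benchmark is all "test".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = cfg.seed
    n_train = 0 if cfg.n_samples == 1 else min(cfg.n_train, cfg.n_samples - 1)
    entries = []
    for i in range(cfg.n_samples):
        s = _sample_seed(seed, i)
        split = "train" if i < n_train else "test"
        grid, lab, cells = simulate_sample(cfg, s)
        sample_id = f"sample_{i:02d}"
        img_path = out_dir / f"{sample_id}_image.tif"
        lab_path = out_dir / f"{sample_id}_labels.tif"
        gt_path = out_dir / f"{sample_id}_truth.csv"
        grid.metadata.update({"seed": s, "split": split, "sample_id": sample_id})
        try:
            save_grid(grid, img_path)
            save_labels(lab, lab_path)
            gt_path.write_text(ground_truth_csv(cells))
        except OSError as e:
            raise OSError(f"failed writing sample {sample_id} under {out_dir}: {e}") from e
        entries.append(
            {
                "sample_id": sample_id,
                "split": split,
                "seed": s,
                "image": img_path.name,
                "labels": lab_path.name,
                "truth": gt_path.name,
                "n_cells": len(cells),
            }
        )
    manifest = {"config": cfg.to_dict(), "seed": int(seed), "samples": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Analytic morphometry of skeleton trees (used for fast statistical
# calibration at the measurement-table level; rasterization-free)
# ---------------------------------------------------------------------------


def analytic_tree_volume(tree: SkeletonTree) -> float:
    """Soma sphere plus conical-frustum process volumes (um^3).

    Ignores soma/process and self overlaps; adequate for distribution-level
    simulations where both groups share the same small bias.
    """
    v = 4.0 / 3.0 * np.pi * tree.soma_radius**3
    for p, c in tree.edges():
        if p == 0:
            continue  # soma-to-surface connector has zero length
        L = float(np.linalg.norm(tree.nodes[c] - tree.nodes[p]))
        r0, r1 = tree.radii[p], tree.radii[c]
        v += np.pi * L * (r0 * r0 + r0 * r1 + r1 * r1) / 3.0
    return float(v)


def analytic_tree_area(tree: SkeletonTree) -> float:
    """Soma sphere plus lateral frustum areas (um^2); overlap-naive."""
    a = 4.0 * np.pi * tree.soma_radius**2
    for p, c in tree.edges():
        if p == 0:
            continue
        L = float(np.linalg.norm(tree.nodes[c] - tree.nodes[p]))
        r0, r1 = tree.radii[p], tree.radii[c]
        a += np.pi * (r0 + r1) * np.sqrt((r0 - r1) ** 2 + L * L)
    return float(a)


def sample_morphometry_table(
    cfg: SimulationConfig,
    n_cells: int,
    n_animals: int,
    group: str,
    rng,
):
    """Sample a per-cell morphometry table from the generator's morphology
    distribution (analytic volumes/areas, no rasterization).

    Cells are assigned to ``n_animals`` animals round-robin, mimicking the
    few-cells-per-animal design of the imaging experiments.
    """
    import pandas as pd

    rows = []
    for i in range(n_cells):
        tree = sample_tree(cfg, np.zeros(3), rng)
        soma_v = 4.0 / 3.0 * np.pi * tree.soma_radius**3
        rows.append(
            {
                "cell_id": i + 1,
                "group": group,
                "animal_id": f"{group}_{i % n_animals + 1}",
                "volume_um3": analytic_tree_volume(tree),
                "area_um2": analytic_tree_area(tree),
                "soma_um3": soma_v,
            }
        )
    return pd.DataFrame(rows)
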