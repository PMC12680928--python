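"""End-to-end orchestration of the morphometry pipeline.

``run_sample_arrays`` chains the stages in memory for one stack:
foreground segmentation -> per-sample threshold -> soma detection ->
marker-controlled watershed -> edge exclusion -> consecutive relabeling.
``run_all`` drives a whole benchmark from a config file, writing artifacts
under a run directory with a manifest recording the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .detect import detect_somata
from .errors import ConfigurationError, MissingUpstreamError
from .evaluation import evaluate_split
from .grid import VoxelGrid, load_grid, load_labels, save_labels
from .instance import exclude_edge_instances, relabel_consecutive, watershed_instances
from .morphometry import measure_all
from .semantic import segment_foreground
from .synthgen import SimulationConfig, make_benchmark

log = logging.getLogger("astromorph")

__all__ = ["run_sample_arrays", "run_all", "config_hash", "load_config"]


def config_hash(cfg: dict) -> str:
    """Short stable hash of a config mapping; stamped into every output table."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path) -> SimulationConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("soma_radius_um", "branch_length_um", "psf_sigma_um", "edge_margin_voxels"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def run_sample_arrays(
    grid: VoxelGrid,
    backend: str = "classical",
    confidence_threshold: float = 0.8,
    min_separation_um: float = 16.0,
    smoothing_sigma_um: float = 0.4,
    threshold_percentile: float = 1.0,
    edge_margin=(0, 1, 1),
    connectivity: int = 26,
) -> dict:
    """Run segmentation -> detection -> watershed -> edge exclusion on one
    stack; returns the intermediate results keyed by stage."""
    fg = segment_foreground(grid, backend=backend,
                            smoothing_sigma_um=smoothing_sigma_um,
                            q=threshold_percentile)
    detections = detect_somata(grid, fg, backend=backend,
                               confidence_threshold=confidence_threshold,
                               min_separation_um=min_separation_um)
    labels = watershed_instances(grid, detections, fg.sample_threshold,
                                 connectivity=connectivity)
    labels, excluded = exclude_edge_instances(labels, edge_margin)
    labels = relabel_consecutive(labels)
    return {
        "foreground": fg,
        "detections": detections,
        "labels": labels,
        "excluded_edge_ids": excluded,
    }


def run_all(config: SimulationConfig | str | Path, out_dir, seed: int,
            pipeline_params: dict | None = None) -> dict:
    """Simulate a benchmark, process every sample, measure retained instances,
    and evaluate the test split. Deterministic for a fixed (config, seed)."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg.to_dict())
    params = pipeline_params or {}

    t0 = time.time()
    bench_dir = out_dir / "benchmark"
    manifest = make_benchmark(cfg, bench_dir, seed)
    log.info("simulate: %d samples in %.1fs -> %s",
             cfg.n_samples, time.time() - t0, bench_dir)

    import pandas as pd

    rec_frames, sholl_frames = [], []
    for entry in manifest["samples"]:
        t1 = time.time()
        grid = load_grid(bench_dir / entry["image"])
        result = run_sample_arrays(grid, edge_margin=tuple(cfg.edge_margin_voxels), **params)
        save_labels(result["labels"], out_dir / f"{entry['sample_id']}_instances.tif")
        rec, sholl = measure_all(result["labels"], grid, result["detections"],
                                 sample_id=entry["sample_id"],
                                 edge_margin=tuple(cfg.edge_margin_voxels))
        rec["config_hash"] = chash
        sholl["config_hash"] = chash
        rec_frames.append(rec)
        sholl_frames.append(sholl)
        log.info("sample %s: %d instances in %.1fs", entry["sample_id"],
                 len(rec), time.time() - t1)

    morpho = pd.concat(rec_frames, ignore_index=True)
    sholl = pd.concat(sholl_frames, ignore_index=True)
    morpho.to_csv(out_dir / "morphometry.csv", index=False)
    sholl.to_csv(out_dir / "sholl.csv", index=False)

    report = evaluate_split(bench_dir / "manifest.json", pipeline_params=params,
                            out_path=out_dir / "evaluation.json")

    run_manifest = {
        "config": cfg.to_dict(),
        "config_hash": chash,
        "seed": int(seed),
        "pipeline_params": params,
        "outputs": ["benchmark", "morphometry.csv", "sholl.csv", "evaluation.json"],
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True, default=str))
    return {"manifest": run_manifest, "evaluation": report, "morphometry": morpho,
            "sholl": sholl}


def require_artifact(path, stage: str):
    """Raise a MissingUpstreamError naming the missing stage artifact."""
    path = Path(path)
    if not path.exists():
        raise MissingUpstreamError(
            f"missing upstream artifact {path} (run the {stage!r} stage first)")
    return path
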