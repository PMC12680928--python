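"""Instance-level evaluation: detection precision/recall and true-positive IoU.

Predicted and ground-truth instances are matched one-to-one, greedily in
descending IoU order; pairs with IoU >= 0.5 (default) are true positives.
Precision = TP/(TP+FP), recall = TP/(TP+FN), and the segmentation quality of
the matches is the arithmetic mean IoU over true positives only -- only true
positives feed the final volume and area measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingUpstreamError
from .grid import LabelVolume, load_grid, load_labels

__all__ = [
    "MatchResult",
    "EvalReport",
    "match_instances",
    "detection_metrics",
    "tp_iou",
    "evaluate_split",
]


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # columns gt_id, pred_id, iou (true positives only)
    fp_ids: list[int]
    fn_ids: list[int]
    n_gt: int
    n_pred: int

    @property
    def n_tp(self) -> int:
        return len(self.pairs)


@dataclass
class EvalReport:
    n_gt: int
    n_pred: int
    n_tp: int
    n_fp: int
    n_fn: int
    precision: float
    recall: float
    mean_tp_iou: float | None  # None when there are no true positives
    degenerate: bool = False  # 0/0 precision or recall reported as 0
    matches: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "n_gt": self.n_gt, "n_pred": self.n_pred, "n_tp": self.n_tp,
            "n_fp": self.n_fp, "n_fn": self.n_fn,
            "precision": self.precision, "recall": self.recall,
            "mean_tp_iou": self.mean_tp_iou, "degenerate": self.degenerate,
            "matches": self.matches,
        }
        return d


def _pair_ious(pred: np.ndarray, gt: np.ndarray) -> pd.DataFrame:
    """IoU for every overlapping (gt, pred) label pair via a joint histogram."""
    both = (pred > 0) | (gt > 0)
    p, g = pred[both].astype(np.int64), gt[both].astype(np.int64)
    pred_sizes = dict(zip(*np.unique(p[p > 0], return_counts=True)))
    gt_sizes = dict(zip(*np.unique(g[g > 0], return_counts=True)))
    key = g * (int(pred.max()) + 1) + p
    sel = (g > 0) & (p > 0)
    uniq, counts = np.unique(key[sel], return_counts=True)
    rows = []
    for k, inter in zip(uniq, counts):
        gid, pid = divmod(int(k), int(pred.max()) + 1)
        union = gt_sizes[gid] + pred_sizes[pid] - inter
        rows.append({"gt_id": gid, "pred_id": pid, "iou": inter / union})
    return pd.DataFrame(rows, columns=["gt_id", "pred_id", "iou"])


def match_instances(
    pred: LabelVolume, gt: LabelVolume, iou_threshold: float = 0.5
) -> MatchResult:
    """Greedy one-to-one matching of predicted to ground-truth instances in
    descending IoU order; pairs at or above ``iou_threshold`` are TP."""
    if pred.shape != gt.shape:
        raise ConfigurationError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    cand = _pair_ious(pred.labels, gt.labels)
    cand = cand[cand.iou >= iou_threshold]
    cand = cand.sort_values(["iou", "gt_id", "pred_id"],
                            ascending=[False, True, True]).reset_index(drop=True)
    used_g, used_p, keep = set(), set(), []
    for row in cand.itertuples():
        if row.gt_id in used_g or row.pred_id in used_p:
            continue
        used_g.add(row.gt_id)
        used_p.add(row.pred_id)
        keep.append({"gt_id": int(row.gt_id), "pred_id": int(row.pred_id),
                     "iou": float(row.iou)})
    pairs = pd.DataFrame(keep, columns=["gt_id", "pred_id", "iou"])
    gt_ids = set(int(i) for i in gt.ids())
    pred_ids = set(int(i) for i in pred.ids())
    return MatchResult(
        pairs=pairs,
        fp_ids=sorted(pred_ids - used_p),
        fn_ids=sorted(gt_ids - used_g),
        n_gt=len(gt_ids),
        n_pred=len(pred_ids),
    )


def detection_metrics(match: MatchResult) -> tuple[float, float, bool]:
    """(precision, recall, degenerate): 0/0 is reported as 0 with the
    degenerate flag set, never as a missing value."""
    tp, fp, fn = match.n_tp, len(match.fp_ids), len(match.fn_ids)
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, degenerate


def tp_iou(match: MatchResult) -> float | None:
    """Mean IoU over true-positive pairs; None (flagged missing) without TPs."""
    if match.n_tp == 0:
        return None
    return float(match.pairs.iou.mean())


def report_from_match(match: MatchResult) -> EvalReport:
    precision, recall, degenerate = detection_metrics(match)
    return EvalReport(
        n_gt=match.n_gt, n_pred=match.n_pred, n_tp=match.n_tp,
        n_fp=len(match.fp_ids), n_fn=len(match.fn_ids),
        precision=precision, recall=recall,
        mean_tp_iou=tp_iou(match), degenerate=degenerate,
        matches=[dict(m) for m in match.pairs.to_dict("records")],
    )


def evaluate_split(
    manifest: dict | str | Path,
    benchmark_dir: str | Path | None = None,
    split: str = "test",
    iou_threshold: float = 0.5,
    pipeline_params: dict | None = None,
    out_path: str | Path | None = None,
) -> dict:
    """Run the full classical pipeline on every sample of a benchmark split
    and report per-sample and pooled (micro-averaged) detection metrics, mean
    TP IoU, and the matched-instance volume recovery error.

    Pooled counts are summed over samples before precision/recall; pooled mean
    TP IoU averages IoU over all pooled true-positive pairs. The volume error
    compares, for each true positive, the predicted instance volume with the
    ground-truth instance volume (only true positives are measured).
    """
    from .pipeline import run_sample_arrays  # late import to avoid a cycle

    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        if not manifest_path.exists():
            raise MissingUpstreamError(f"benchmark manifest not found: {manifest_path}")
        benchmark_dir = manifest_path.parent
        manifest = json.loads(manifest_path.read_text())
    if benchmark_dir is None:
        raise ConfigurationError("benchmark_dir required when manifest is a dict")
    benchmark_dir = Path(benchmark_dir)
    params = pipeline_params or {}

    entries = [e for e in manifest["samples"] if e["split"] == split]
    if not entries:
        raise MissingUpstreamError(f"no samples with split {split!r} in manifest")

    per_sample = {}
    pooled_pairs = []
    pooled = {"n_gt": 0, "n_pred": 0, "n_tp": 0, "n_fp": 0, "n_fn": 0}
    rel_errors = []
    edge_margin = tuple(manifest["config"].get("edge_margin_voxels", (0, 1, 1)))

    for e in entries:
        grid = load_grid(benchmark_dir / e["image"])
        gt = load_labels(benchmark_dir / e["labels"])
        result = run_sample_arrays(grid, edge_margin=edge_margin, **params)
        pred = result["labels"]
        gt_kept, _ = _filter_edges(gt, edge_margin)
        match = match_instances(pred, gt_kept, iou_threshold)
        report = report_from_match(match)
        per_sample[e["sample_id"]] = report.to_dict()
        pooled["n_gt"] += report.n_gt
        pooled["n_pred"] += report.n_pred
        pooled["n_tp"] += report.n_tp
        pooled["n_fp"] += report.n_fp
        pooled["n_fn"] += report.n_fn
        pooled_pairs.extend(match.pairs.iou.tolist())
        vox = pred.voxel_volume_um3
        for m in match.pairs.itertuples():
            pv = pred.voxel_count(m.pred_id) * vox
            gv = gt_kept.voxel_count(m.gt_id) * vox
            rel_errors.append(abs(pv - gv) / gv)

    tp, fp, fn = pooled["n_tp"], pooled["n_fp"], pooled["n_fn"]
    out = {
        "split": split,
        "per_sample": per_sample,
        "pooled": {
            **pooled,
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "recall": tp / (tp + fn) if tp + fn else 0.0,
            "mean_tp_iou": float(np.mean(pooled_pairs)) if pooled_pairs else None,
            "volume_median_rel_error": float(np.median(rel_errors)) if rel_errors else None,
        },
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(out, indent=2, sort_keys=True))
    return out


def _filter_edges(labels: LabelVolume, margin):
    from .instance import exclude_edge_instances

    return exclude_edge_instances(labels, margin)
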