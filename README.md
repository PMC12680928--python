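# astromorph

3D morphometry of fluorescent astrocytes, packaged as a tested, desk-scale
pipeline. Astrocytes are star-shaped glial cells whose volume responds to the
osmotic state of the brain's extracellular space: swelling raises cell volume
and surface area while leaving the branching architecture unchanged. Telling
those two effects apart in confocal z-stacks requires per-cell instance
segmentation, physically calibrated volume/area measurement, and Sholl
profiling — plus group statistics that respect the animal/cell hierarchy.
This package implements the full chain and, crucially, a synthetic-astrocyte
image generator with exact ground truth so that every stage can be verified
quantitatively without access to microscope data.

It is intended for image-analysis and quantitative-neurobiology groups who
want a reproducible, inspectable alternative to GUI pipelines for this class
of measurement, and for method developers who need a ground-truthed benchmark
for 3D instance segmentation of sparse branched cells.

## The pipeline

1. **Synthetic volumes** (`astromorph.synthgen`) — sparse astrocyte-like
   cells (spherical soma, tapering tortuous processes) sampled as skeleton
   trees, rasterized onto an anisotropic voxel grid (0.93 µm axial steps
   across a 143 µm field by default), blurred with a Gaussian PSF and
   corrupted with Gaussian or Poisson noise. Ground truth: instance labels,
   soma centers, voxel-count volumes, marching-cubes surface areas.
2. **Semantic segmentation** (`astromorph.semantic`) — foreground
   probability, binary mask, and the per-sample intensity threshold τ (the
   1st percentile of in-mask intensities), which later bounds the lowest
   intensity a watershed instance may include.
3. **Soma detection** (`astromorph.detect`) — anisotropy-aware Euclidean
   distance transform of the mask; local maxima with minimum physical
   separation; peak-normalized confidences filtered at 0.8.
4. **Instance segmentation** (`astromorph.instance`) — marker-controlled
   watershed flooding the negated-intensity relief, restricted to voxels
   ≥ τ; deterministic FIFO tie-breaking; border-touching instances excluded.
5. **Morphometry** (`astromorph.morphometry`) — volume = voxel count × dz·dy·dx;
   surface area = Σ triangle areas of the marching-cubes isosurface; soma
   volume via morphological opening; Sholl profiles (crossings of concentric
   spheres at 2 µm intervals) on 3D skeletons.
6. **Evaluation** (`astromorph.evaluation`) — greedy one-to-one IoU matching;
   precision = TP/(TP+FP), recall = TP/(TP+FN), mean IoU over true positives.
7. **Statistics** (`astromorph.stats`) — two-tailed Mann–Whitney tests (exact
   for small tie-free samples), iterated Grubbs outlier exclusion, per-animal
   aggregation, percent change of group means, and the 3-parameter Hill fit
   f(x) = a·x^b/(c^b + x^b) for spike-count vs injected-current curves.

## Worked example

```python
import numpy as np
from astromorph import SimulationConfig, simulate_sample, run_sample_arrays, measure_all
from astromorph.evaluation import match_instances, report_from_match
from astromorph.instance import exclude_edge_instances

cfg = SimulationConfig()                        # 30 x 240 x 240 voxels, 5 cells
grid, truth, cells = simulate_sample(cfg, seed=42)

result = run_sample_arrays(grid, edge_margin=cfg.edge_margin_voxels)
print("tau =", round(result["foreground"].sample_threshold, 1))
print("detections:", len(result["detections"]),
      "confidences:", np.round(result["detections"].confidences, 3))

records, sholl = measure_all(result["labels"], grid, result["detections"])
print(records[["cell_id", "volume_um3", "area_um2", "soma_um3"]].round(1).to_string(index=False))

truth_kept, _ = exclude_edge_instances(truth, cfg.edge_margin_voxels)
report = report_from_match(match_instances(result["labels"], truth_kept))
print(f"precision={report.precision:.3f} recall={report.recall:.3f} "
      f"mean_tp_iou={report.mean_tp_iou:.3f}")
```

Output:

```
tau = 235.8
detections: 5 confidences: [1.    0.943 0.937 0.931 0.891]
 cell_id  volume_um3  area_um2  soma_um3
       1      1407.2    1537.6     656.7
       2      1246.7    1328.3     622.4
       3      1171.8    1206.1     663.6
       4      1399.6    1417.5     767.6
       5      1265.5    1268.8     687.4
precision=1.000 recall=1.000 mean_tp_iou=0.918
```

All five simulated astrocytes are found (confidences well above the 0.8
cutoff), each measured volume is the voxel-count volume of its watershed
instance in µm³, and every instance matches its ground-truth cell one-to-one
with a mean IoU of 0.92.

The same stages are available from the shell:

```bash
astromorph simulate --out bench --seed 7
astromorph all --out run --seed 7          # simulate + segment + measure + evaluate
astromorph evaluate --manifest bench/manifest.json --out eval
```

## Layout

```
src/astromorph/     library (generator, pipeline stages, statistics, CLI)
tests/              pytest suite, including end-to-end acceptance checks
scripts/            acceptance script
docs/methods.md     model, parameter and design documentation
```
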