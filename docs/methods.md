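# Methods

## Scope and conventions

The package measures astrocyte morphology in 3D fluorescence z-stacks:
instance segmentation of individual cells, voxel-count volume, marching-cubes
surface area, soma volume, Sholl profiles, and the group statistics used to
compare a control with a perturbed population. All coordinates follow the
voxel-center convention — the physical position of voxel (z, y, x) is
`origin + index * spacing`, with spacing `(dz, dy, dx)` in µm — and all
bounding boxes are half-open in voxel indices. Voxel spacing always comes
from an explicit JSON sidecar or config; TIFF resolution tags are never
trusted, and a missing sidecar is a hard error.

## Synthetic astrocytes

The generator exists so every downstream stage can be scored against exact
ground truth. A cell is a skeleton tree: a spherical soma (radius drawn from
5.0–5.6 µm) with 6 ± 1 primary processes, each a tortuous chain of ~3 µm
segments with total length 14–22 µm, tapering linearly from a 1.6 µm root
radius to a 0.9 µm tip, and bifurcating once with probability 0.4. Somata are
placed by rejection sampling with a 32 µm minimum separation inside a lateral
margin; infeasible densities raise an explicit placement error after a
bounded number of restarts.

Rasterization labels a voxel with cell k iff its center lies inside k's soma
sphere or within the local process radius of one of k's edges; voxels claimed
by several cells go to the nearest centerline with ties to the lower cell id.
Ground-truth volume is the voxel count times the voxel volume — the same
convention the measurement stage uses — and ground-truth surface area is the
marching-cubes mesh area of the cell's own binary mask, so that
area-recovery tests isolate segmentation error from meshing error.
Rendering adds a constant background (100), an amplitude step (400) on the
foreground, an anisotropic Gaussian PSF (σ = 0.8 µm axial, 0.4 µm lateral),
and Gaussian noise (SD 8) by default; Poisson noise is available by config.
Intensities are clipped at zero, so background levels should sit several
noise SDs above zero if unbiased background statistics matter.

The default grid emulates a confocal acquisition of cortical astrocytes:
30 z-slices at 0.93 µm spanning a square 143 µm field. The default lateral
sampling is 240 px (0.596 µm/px) — the package's desk-scale choice; the
full 512 px (0.279 µm/px) sampling of the original acquisitions is one
config value away (`lateral_px=512`) and the geometry helper reproduces the
(30, 512, 512) stack shape exactly. A benchmark is 7 samples, the first 5
assigned to "train" and the rest to "test"; a single-sample benchmark is all
"test". Every sample records its seed, spacing and split in a JSON sidecar,
and re-running a manifest reproduces byte-identical ground-truth CSVs.

What the generator does *not* emulate: depth-dependent PSF, spectral
bleed-through, vasculature or neuronal background structures, motion
artifacts, and the fine sub-micron process fragments of real astrocytes
(process radii are kept ≥ 0.9 µm so rasterized tubes stay connected at the
default sampling). Passing tests therefore demonstrate correctness of the
measurement machinery under controlled geometry and noise, not performance
on real tissue. Cell-to-cell volume variability (~7% CV) is also narrower
than in tissue; group comparisons on synthetic data are correspondingly
better powered than the same design on real cells.

## Segmentation and the per-sample threshold

The classical semantic backend smooths the stack with an anisotropy-aware
Gaussian (σ = 0.4 µm, converted per axis by the spacing), applies Otsu's
global threshold, and squashes `(smoothed − threshold) / noise-scale`
through a logistic to obtain a pseudo-probability, so the `prob ≥ 0.5`
contract is independent of the backend. The noise scale is the robust SD
(MAD × 1.4826) of the high-frequency residual. The per-sample threshold τ is
the q-th percentile (default q = 1) of *raw* intensities over mask voxels —
near the dimmest genuine signal but robust to noise outliers; it is
undefined (an explicit error) when the mask is empty or covers the whole
stack. Learnable backends (a 3D encoder–decoder for semantics, a heatmap
regressor for detection) are deliberately out of scope in this build: the
classical backends meet the benchmark targets on CPU, and the optional
torch dependency is not part of the supported environment.

Soma detection computes the Euclidean distance transform of the mask with
physical sampling, smooths it (σ = 1 µm), and takes local maxima with a
minimum separation (default 16 µm, half the minimum soma separation of the
generator). Confidence is the peak value normalized by the sample's largest
peak; detections below the 0.8 cutoff are discarded. Somata are by far the
thickest structures (≈ 5 µm radius vs ≤ 1.6 µm processes), so genuine somata
score near 1.0 and branch junctions near 0.3 — the cutoff separates them
with a wide margin.

## Watershed instancing

Instances are grown by marker-controlled watershed on the negated intensity
relief (brighter floods first), restricted to voxels with intensity ≥ τ, with
26-connectivity. The flood is an explicit best-first priority queue with two
pinned determinism rules: equal-priority voxels pop in FIFO insertion order,
and markers are seeded in lexicographic (z, y, x) order. This makes the
output bit-reproducible and lets the test suite demand voxel-for-voxel
equality with an independently written brute-force flood (and agreement with
`skimage.segmentation.watershed` on tie-free reliefs). Markers landing on
sub-τ voxels are snapped to the nearest in-domain voxel within 3 voxels,
else dropped with a warning.

Instances whose bounding box intersects the outer margin shell of the grid
are excluded from measurement. The default margin is 1 voxel laterally and 0
axially: physical sections are axially truncated by the slicing itself, so
face contact in z is expected and not disqualifying, while lateral contact
means an unknown fraction of the cell is outside the field. A
minimum-captured-process criterion (centered somata with ≥ 10–12 µm of
processes in the field) is the inclusion rule used with manually curated
acquisitions; the margin rule is its automated counterpart and the default
here.

## Morphometry

* **Volume** — voxel count × dz·dy·dx.
* **Surface area** — marching cubes at level 0.5 on the binary instance mask
  with physical spacing, padded by one zero voxel so crop-boundary instances
  still close into watertight meshes; area is the sum of triangle areas. On
  digital solids at 0.5 µm sampling this is within ~8% for a 10 µm sphere
  and ~3% for a 10 µm cube (marching cubes chamfers corners and ridges).
* **Soma volume** — connected component containing the soma center after
  opening the instance with a 2 µm ball (distance-transform erosion +
  dilation, anisotropy-aware). Opening removes all processes thinner than
  the ball while shaving only a sub-voxel shell off the soma (~3% on a 5 µm
  digital sphere). Radius 0 degenerates to the full instance.
* **Sholl profile** — the skeleton (3D topological thinning; leaf spurs
  < 2 µm pruned; adjacent junction voxels merged for endpoint/junction
  censuses) is intersected with concentric spheres of radius 2, 4, … µm
  around the soma center. A crossing is an edge whose endpoint distances
  straddle the radius (`min < r ≤ max`), counted with multiplicity; tangent
  touches do not count. Sholl is computed in true 3D; real acquisitions are
  axially truncated, which depresses counts equally in compared groups.

## Evaluation

Predicted and ground-truth instances are matched greedily in descending IoU
order, one-to-one, with TP at IoU ≥ 0.5. Precision, recall and the mean IoU
over true positives are reported per sample and pooled (micro-averaged) over
the test split; only true positives enter volume/area recovery statistics.
0/0 precision or recall is reported as 0 with an explicit degenerate flag —
never as a missing value — so thresholds remain well-defined; a missing mean
TP IoU (no true positives) is `None`. On the default benchmark the classical
pipeline reaches pooled precision = recall = 1.0, mean TP IoU ≈ 0.92, and a
median matched-volume error of ~8%. The volume error is a small systematic
overestimate: τ sits at the 1st percentile of mask intensities, slightly
below the half-amplitude PSF contour, so instances carry a thin blur halo.

## Statistics

* **Mann–Whitney** — two-tailed; exact (doubled one-sided tail, capped at 1)
  when the pooled sample is tie-free with ≤ 20 values, tie-corrected
  continuity-corrected normal approximation otherwise. The exact path is
  verified against full enumeration of all C(n+m, n) labelings.
* **Grubbs** — iterated two-sided test at α = 0.05 with t-distribution
  critical values `G = (n−1)/√n · √(t²/(n−2+t²))`, `t = t_{α/2n, n−2}`;
  removes the most extreme value until no rejection; n < 3 or zero spread is
  a warned no-op.
* **Percent change** — `100 · (mean_cKO − mean_CTR)/mean_CTR`, reported raw
  and rounded; the bundled microdialysis group means reproduce the published
  ~73% (glutamine), ~79% (post-K glutamine) and ~42% (alanine) increases.
* **Hill fit** — least squares of `f(x) = a·x^b/(c^b + x^b)` over positive
  current steps only (x^b is ill-defined for x ≤ 0 with real b), bounded
  positive parameters, deterministic multistart (a₀ = max response, c₀ =
  step nearest half-max, b₀ ∈ {1, 2, 4}; best RSS wins). The reported
  "current at maximum frequency" is the first observed step attaining the
  maximal observed response, not a fitted quantity, because the fitted
  plateau is reached only asymptotically.
* **Swelling report** — per-metric group means, percent change, cell-level
  and per-animal-mean Mann–Whitney p-values, and per-radius Sholl
  comparisons. Within the report, the three morphometric p-values form one
  Holm family and the ~15 Sholl radii another: the radii are numerous and
  strongly correlated, and without family-wise control a null comparison
  would flag some radius in roughly half of all runs. Raw p-values are
  always reported alongside the adjusted ones.

Calibration simulations draw measurement tables directly from the
generator's morphology distribution using analytic skeleton volumes (soma
sphere + conical frustums) — rasterization-free, so 200-replicate null
calibrations run in seconds. The in-silico swelling experiment instead
rasterizes and measures every cell (15 per group, 5 animals each, one cell
per grid): scaling process radii ×1.2 with an unchanged branching program
raises measured volume by ~25% (cell-level exact Mann–Whitney p < 10⁻³)
while no Sholl radius survives adjustment — the volume-up /
branching-unchanged dissociation expected of osmotic swelling.

## Problem sizes and determinism

Default problem sizes: 7-sample benchmark of (30, 240, 240) voxel stacks
with 5 cells each; 20 randomized ≤ 32³ reliefs for the watershed oracle; 100
enumeration checks and 200 null replicates for the statistics; 30 rasterized
cells for the swelling experiment. Every operation is a pure function of
(config, seed): reruns are bit-identical, including TIFF/CSV/JSON artifacts,
and all output tables carry a config hash so tables from different
configurations cannot be silently aggregated.

## Known limitations

Classical backends only (no learned models bundled); single-channel
intensity model; no deconvolution; the soma segmentation is an
opening-based operational definition, not a biological compartment boundary;
Sholl profiles from voxel skeletons inherit thinning artifacts on bumpy
tubes (mitigated, not eliminated, by spur pruning); and the evaluation
assumes ground-truth instance labels on the same grid as the prediction.
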