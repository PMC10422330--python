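# Methods

This note documents the models and procedures implemented in `reef3d`,
the choices made where the design was open, and what the synthetic
test conditions do and do not establish about real reef data.

## Problem setting

The package operates on the standard products of close-range
underwater photogrammetry: a co-registered orthomosaic (RGB) and
digital surface model (DSM) at ~1 mm grid spacing in a shared metric
frame, plus dense point clouds and triangle meshes in the same frame.
It answers two questions about branching-coral habitat surveyed at two
epochs: *where* is live and dead coral (semantic segmentation), and
*how has the structure changed* (height change, multi-scale rugosity
and roughness, stratified by semantic class).

All grids are axis-aligned and north-up with cell-center coordinates:
pixel (row, col) maps to world
`(x0 + (col + 0.5)·cell, y0 − (row + 0.5)·cell)`. Heights are metres
internally; change maps are reported in millimetres (×1000 on output
only). Nodata sentinels are −9999.0 for float rasters and 255 for
labels. Every operation that consumes two rasters first asserts exact
grid agreement; mis-registered inputs never reach computation.

## Segmentation network

The segmentation model is a DeepLabv3+-style encoder-decoder over a
4-channel input formed by channel-wise concatenation of RGB and the
DSM patch. The encoder is a small residual convolutional stack whose
convolutions are *shape-aware* (ShapeConv): each K×K receptive-field
window `P` is decomposed per channel into a base component (its
spatial mean) and a shape component (the residual),

```
base  = mean(P),   shape = P − base,
P′    = w_base · base + w_shape ∘ shape,
out   = kernel ⋆ P′,
```

with `w_base` (one scalar per input channel) and `w_shape` (one
weight per channel and kernel position) learnable and initialised to
1, so an untrained layer is exactly a vanilla convolution. After
training the weights fold into the kernel
(`ShapeConv2d.folded()`), so inference carries no extra cost. The
decomposition lets the network reweight relative relief (shape)
against absolute level (base), which is what makes the height channel
informative for coral boundaries. ShapeConv replaces encoder/backbone
convolutions only; ASPP and the decoder use plain and
depthwise-separable convolutions.

Multi-scale context comes from atrous spatial pyramid pooling (a 1×1
branch, dilated 3×3 branches, and a global-average image branch); the
decoder upsamples, fuses a low-level encoder tap, applies a
depthwise-separable convolution and classifies into three classes
(background / live coral / dead coral).

Training minimises the hybrid objective

```
L = L_CE + μ · L_IoU ,     μ = 0.4 by default,
```

where `L_CE` is mean pixel cross entropy over non-ignored pixels and
`L_IoU = 1 − mean_c I_c/U_c` is a soft (probability-valued)
intersection-over-union averaged over the classes present in the
labels or the argmax prediction, with `I_c = Σ p_c y_c` and
`U_c = Σ (p_c + y_c − p_c y_c)`. CE supplies a smooth per-pixel
gradient; the IoU term is map-level and pushes whole regions toward
their target shapes. The IoU average includes the background class by
default (a `foreground_only` switch is exposed). Gradients of both
terms are analytic and verified against finite differences in the
test suite.

Ablation variants are configuration switches: `use_dsm=False` is the
RGB-only baseline (Model A), `use_shapeconv=False` with the DSM is the
plain-convolution multi-modal variant (Model B), and both switches on
is the full model.

### Choices the architecture leaves open

- **Backbone**: no published backbone is mandated; the encoder is a
  configurable residual stack with two presets — `tiny` (three
  encoder stages, ≤24 channels, output stride 4; trains on one CPU
  core) and `full` (wider/deeper, for real scenes). The test suite and
  benchmarks use `tiny` — the package is NumPy-only and CPU-bound, so
  problem sizes are chosen to keep a full training run in minutes.
- **Input normalisation**: RGB is scaled to [0,1] and standardised
  with per-channel training-set statistics. The DSM patch has its
  median subtracted and is divided by a fixed 0.05 m relief scale:
  this removes absolute depth (which varies across a reef and carries
  no class information) while preserving relief amplitude in
  physically meaningful units.
- **Optimiser**: Adam (lr 1e-3 to 2e-3, cosine decay). Batches are
  shuffled per epoch; augmentation applies an independent random
  90°-multiple rotation per patch. Rotations are restricted to
  multiples of 90° so the height channel is never interpolated;
  translations are jittered crop offsets taken from the source rasters
  at extraction time.
- **Upsampling** in the decoder is nearest-neighbour (factor 2 twice);
  on the easy synthetic benchmarks this is indistinguishable from
  bilinear and its adjoint is exact.

## Tiling and stitching

Scenes are tiled on a sliding grid: window 448, stride 224 by default
(50 % overlap), giving `floor((extent − window)/stride) + 1` windows
per axis; trailing remainders are dropped. Patches more than 50 %
nodata are excluded from training. Predictions are stitched by
averaging class probabilities on overlaps and taking the argmax, ties
broken toward the lower class id; uncovered cells are nodata.
Stitching one-hot ground truth reproduces the ground truth exactly.
Cross-validation uses shuffled round-robin assignment into five folds
whose sizes differ by at most one.

## Evaluation metrics

From the confusion matrix `n_ij` (true i, predicted j, nodata pixels
excluded): mean pixel accuracy is the mean over truth-present classes
of `n_ii / Σ_j n_ij`; mean IoU is the mean over present classes of
`n_ii / (row_i + col_i − n_ii)`. Classes absent from both truth and
prediction are dropped from the averages.

## Terrain analysis

**Slope/aspect** use Horn's 3×3 weighted finite differences (the
default of common GIS terrain tooling). Aspect is the downslope
azimuth clockwise from grid north; flat cells get aspect 0, which is
immaterial because `sin(slope) = 0` there. Border cells and cells
with any nodata neighbour are nodata.

**VRM** (vector ruggedness measure): per cell the unit surface normal
is decomposed as `(sin s·sin a, sin s·cos a, cos s)`; over an odd
w×w window the resultant `R = (Σnx, Σny, Σnz)` gives
`vrm = 1 − |R|/w²` in [0, 1] — exactly 0 on any constant-gradient
plane (including tilted ones) and larger as normals disperse. Window
sums use exact summed-area tables, so a flat DSM yields exactly 0.
Windows containing any nodata normal are nodata (nodata-strict;
pre-fill holes if that is too conservative). Class assignment for
stratified summaries uses each cell's own mask value, not a
window-majority vote.

**Height change** is the pixel-wise DSM difference (epoch 2 − epoch 1)
in mm. Distributions are summarised by n, min, quartiles, max, mean
and sd; the median is the headline statistic because growth/mortality
mixtures are strongly skewed. Histograms default to 1 mm bins over
±50 mm — a display truncation that is never applied to the
statistics.

## Point-cloud roughness

Roughness of a point at radius r is its perpendicular distance to the
total-least-squares plane (smallest-eigenvector of the neighbour
covariance) fitted to all points within r, the query point excluded
from its own fit — including it would bias every estimate toward
zero, and the convention changes values, so it is fixed and
documented. At least 3 non-collinear neighbours are required
(collinearity detected by eigenvalue ratio < 1e-12), otherwise the
point gets NaN; neighbour counts are not capped. Neighbour search uses
a k-d tree; the contract is exactness, verified against an O(N²)
scan. Roughness is invariant under rigid motions and scales linearly
under uniform scaling (with the radius scaled identically). Default
radii 20/50/100 mm span polyp to colony scale.

## Mesh projection

Meshes built from DSMs are height fields (one vertex per valid cell,
two triangles per complete quad, all face normals +z), so
vertical-ray projection of rasters onto vertices is exact. Labels use
nearest-cell lookup (categorical data is never interpolated); scalars
use bilinear interpolation on the cell-center grid. Vertices outside
the raster or over nodata stay unset (255 / NaN). For real
photogrammetric meshes with overhangs, vertical projection is an
approximation: the highest-surface attribution wins. Class colors are
dark pink (live), light pink (dead) and grey (background); change
scalars use a red-white-blue diverging map over ±50 mm with values
beyond the range clamped for display. Projection is idempotent. PLY
export keeps per-vertex colors and scalar properties; OBJ export is
geometry-only (documented limitation).

## Synthetic scenes

The generator emulates a ~1 m² fore-reef quadrat at 1 mm grid
spacing: a gently undulating sandy substrate (smoothed mm-scale
noise), ~10 % rocky cover, and non-overlapping hemispherical-cap
colonies (default 4–9 cm radius, 5–15 cm height) carrying ~8 mm
branch-ridge relief. Live colonies render dark pink, dead ones pale
pink with the skeleton relief intact (recently dead branching coral
keeps a clear white structure); sand is tan, rock grey. A linear
illumination gradient (±25 %) and per-pixel RGB noise emulate
uneven underwater lighting. The dead-coral color is configurable:
setting it to the sand color creates the color-confusable condition
under which only the height channel separates dead coral from
substrate — the condition used for the RGB vs RGB+DSM ablation.

The epoch delta applies uniform vertical growth (mm) to surviving
live colonies, relabels a floor-fraction of live colonies to dead
with the DSM untouched, and erases a fraction of colonies back to the
stored substrate. Background cells are conserved bit-exactly, so the
prescribed growth is recoverable: the median DSM difference over
surviving live cells equals the prescribed value exactly in the
noise-free default, and within 1.5× the noise sd when per-epoch
re-noising is enabled. Colonies are placed by rejection sampling with
a minimum gap, keeping the truth table and the label components in
1:1 correspondence.

What the synthetic scenes do **not** model: photorealistic texture,
water-column optics, occlusions and reconstruction holes, algal
turf succession on dead skeletons, or photogrammetric noise
correlation. Passing benchmarks on these scenes demonstrates that the
implementation is correct and that the height channel carries the
intended signal under controlled conditions; it does not certify
segmentation accuracy on real surveys.

## Benchmarks the test suite runs

- Smoke benchmark: tiny model, 200 easy 64×64 patches (160 train /
  40 validation), 30 epochs — validation mIoU reaches ≥ 0.7 (typically
  ≈ 0.97 by epoch 5).
- Ablation: on color-confusable scenes (dead = sand color), mean best
  mIoU over 3 seeds of the RGB+DSM model exceeds the RGB-only model.
- Growth recovery: two-epoch scene with 10 mm prescribed growth —
  live-class median change is exactly 10 mm, scene-wide median
  strictly smaller.
- Scale dependence: live-coral median VRM exceeds background VRM at
  the 21-cell window, and the contrast shrinks by the 101-cell window
  as windows mix coral and substrate.

## Known limitations

- No CRS handling or reprojection: all inputs must already share one
  metric frame (GeoTIFFs carry only pixel scale, tiepoint and nodata
  tags).
- The NumPy network is CPU-bound; the `full` preset is constructible
  and trainable but not sized for million-patch surveys.
- Vertical-ray mesh projection is exact only for height-field meshes.
- VRM windows are nodata-strict, which voids cells near holes.
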