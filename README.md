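# reef3d

Multi-modal semantic segmentation and 3D structural-change analysis
for millimetre-scale coral-reef monitoring products.

Close-range underwater photogrammetry delivers co-registered
orthomosaics (RGB) and digital surface models (DSMs) of reef quadrats
at ~1 mm grid spacing, plus dense point clouds and meshes in the same
metric frame. `reef3d` turns a two-epoch pair of such products into
ecological change measurements for branching-coral habitat:

- **Segmentation** of every pixel into background / live coral / dead
  coral with MMCS-Net, a DeepLabv3+-style encoder-decoder over the
  4-channel RGB+DSM input. The encoder uses *shape-aware convolutions*
  (each K×K window `P` is split into a spatial-mean base and a
  residual shape component, reweighted by learnable weights before the
  kernel product: `P′ = w_b·mean(P) + w_s∘(P − mean(P))`), and
  training minimises the hybrid loss `L = L_CE + μ·L_IoU` (μ = 0.4),
  pairing the smooth per-pixel cross-entropy gradient with a
  map-level soft-IoU term.
- **Height change**: pixel-wise DSM differencing (mm), summarised by
  medians and stratified by the predicted semantic class.
- **Rugosity**: the Vector Ruggedness Measure
  `vrm = 1 − |Σ n̂|/w²` over w×w windows of unit surface normals
  (Horn slope/aspect), and per-point 3D roughness — the distance of a
  point to the total-least-squares plane of its neighbours within
  radii of 20/50/100 mm.
- **3D mapping**: projection of class masks and change maps onto
  height-field meshes with per-vertex colors (PLY).

Because no public dataset pairs mm-scale reef orthomosaics, DSMs and
three-class labels, the package ships a first-class synthetic scene
generator (`reef3d.synthetic`) that builds two-epoch reef quadrats
with *known* growth, mortality and removal — every downstream stage
is testable against ground truth by construction.

The network is implemented in pure NumPy (explicit forward/backward
passes, Adam, analytic loss gradients verified against finite
differences) and trains on a single CPU core with the `tiny` preset.

## Worked example

The `demo` command runs the whole workflow on a synthetic 0.26 m
two-epoch quadrat (6 colonies, 10 mm prescribed growth on surviving
live colonies, a third of live colonies dying between epochs):

```sh
reef3d demo --seed 7 --out run/
```

It generates the scene pair, trains the tiny MMCS-Net on epoch-1
patches, predicts full-scene masks for both epochs, and computes
class-stratified change, VRM and roughness, printing:

```json
{
  "seed": 7,
  "n_patches": 81,
  "val_mPA": 0.961013,
  "val_mIoU": 0.866656,
  "median_change_scene_mm": 0.0,
  "median_change_live_mm": 10.0,
  "prescribed_growth_mm": 10.0,
  "vrm_w11_median_live": 0.43234544893916926,
  "vrm_w11_median_background": 0.3368973967970088,
  "roughness_r20_median_live": 0.0031415649814107278,
  "roughness_r20_median_dead": 0.002913964604042401,
  "roughness_r20_median_background": 0.001354391279386517,
  "mesh_vertices": 65536
}
```

Reading the numbers: the model reaches 0.87 validation mIoU on held-out
patches; the median height change over cells the model labels live is
exactly the prescribed 10 mm, while the scene-wide median is 0 mm
(most of the scene is static substrate — the class median exceeding
the scene median is the expected signature of growth concentrated in
live colonies). Live coral is distinctly more rugged than the sandy
background at the 11-cell VRM window (0.43 vs 0.34) and rougher in
the point cloud at the 20 mm radius (3.1 mm vs 1.4 mm median
point-to-plane distance). Outputs land in `run/`: GeoTIFF rasters,
a model checkpoint, stats CSVs, a roughness-attributed point cloud
and a semantically colored mesh (`mesh_semantic.ply`), each command
writing a `.run.json` sidecar with its parameters and seed.

Individual stages are available as composable commands —
`synth`, `tile`, `split`, `train`, `predict`, `eval`, `vrm`,
`heightchange`, `roughness`, `project-mesh` — and as library functions
(`reef3d.mmcs`, `reef3d.terrain`, `reef3d.roughness`, `reef3d.mesh`).

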