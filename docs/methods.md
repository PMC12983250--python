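# Methods

## Scope and conventions

`canopycomplete` reconstructs the occluded interior of population-scale
crop canopy point clouds and derives yield-related traits from the
completed clouds. All geometry is metric: centimeters, z up, ground plane
z = 0. Organ labels are unsigned 8-bit codes {0 stem, 1 leaf, 2 flower,
3 silique}.

## Procedural plants and plot simulation

Individual plants are parametric: the main stem and branches are tapered
generalized cylinders (6-sided rings), leaves are curved lanceolate
strips that rise at 10–35° and droop toward the tip, flowers are small
spheroids at branch tips, and siliques are prolate spheroids (5–8 cm
long, 0.25–0.35 cm radius) on the upper canopy. Four stage archetypes
(seedling, bolting, flowering, silique) fix ranges for height, organ
counts and organ dimensions; each `(archetype, seed)` pair maps
deterministically to one plant. The archetype defaults are repository
conventions chosen to caricature field-grown rapeseed — in particular
foliage is dense enough (16–26 leaves of 14–24 cm at bolting, leaf area
index ≈ 3.5) that the canopy closes over at the default 25 cm × 28 cm
spacing, because a canopy
that never closes produces almost no interior occlusion and would make
the completion task trivial and unrepresentative. What the generator does
*not* emulate: photogrammetric noise, texture-dependent reconstruction
dropouts, wind deformation, petiole/organ connectivity constraints, and
real morphological covariance between organs. Passing tests therefore
demonstrate that the pipeline and the learning machinery work end to end
under realistic geometric occlusion; they are not evidence about any
specific field dataset.

Plots place 16 plants (4×4; sampled from a same-stage pool with
replacement) on the grid, anchoring each stem/ground intersection at its
grid position. Cross-plant near-duplicate points are removed by a greedy
sweep (threshold 0.1 cm, spatial-hash/KD-tree backed, lower plant index
wins); within-plant density is untouched.

## Occlusion annotation

The simulated UAV rig puts one viewpoint per 10° of azimuth (36 views) on
a circle whose viewing ray is depressed 60° below horizontal at 5 m from
the plot center, i.e. horizontal radius 2.5 m and height 4.33 m. A point
is *occluded* when, for every camera, at least one mesh triangle
intersects the open segment from the point to that camera
(Möller–Trumbore, inclusive edge policy, finite segment). Points lie on
the mesh, so hits closer than ε = 10⁻⁴ × scene bounding-box diagonal to
the segment origin are ignored. A compiled (numba) kernel with per-point
early exit accelerates the triple loop; a vectorized numpy fallback
computes identical labels and both are tested against the literal
triple-loop brute force.

## Blocks and fixed-size resampling

Plot clouds are cut by a sliding window over the horizontal bounding
rectangle (default 4×2 = 8 windows, the long axis getting 4; overlap
optional and 0 by default). Each block is translated to its window center
(x, y and z), never scaled — Chamfer distances stay in cm² throughout.
Oversized blocks are reduced by farthest point sampling (deterministic,
start index 0, ties to the lowest index); undersized blocks keep all
original points and pad with Gaussian-jittered re-draws (σ = 0.05 cm).
The recorded translation restores completed blocks to plot coordinates
exactly.

## Network

**Encoder.** Three nested FPS resolutions (8192/4096/2048 at defaults;
the FPS start point is the point farthest from the centroid, which makes
the selected subset permutation-invariant). Per resolution, five dynamic
graph convolution layers with channels {64, 128, 256, 512, 1024}: each
layer rebuilds a k-nearest-neighbor graph (k = 20) in the current feature
space (coordinates for layer 1), forms edge features concat(center,
neighbor − center), applies a shared linear map, aggregates edges by
channel-wise max, then batch-normalizes and rectifies the aggregated
point features (ReLU commutes with max and the edge bias is absorbed by
the normalization, so this ordering computes the same activations as the
edge-wise variant at an eighth of the memory traffic). The outputs of
layers 2–5 are global-max-pooled and concatenated over the three
resolutions: 3 × (128+256+512+1024) = 5760 latent dimensions — the only
pooling of the stated channel list over three resolutions consistent with
that latent size, so layer 1 feeds later layers but is not pooled. A
`width_scale` multiplies all channel widths (the latent dimension law
3 × Σ channels 2..5 holds at any scale).

**Decoder.** Two fully connected ReLU stages (hidden 1024·width_scale)
compress the latent into a global code. The decoder offers two paths with
the same pyramid structure (two children per parent, linear outputs, no
batch normalization). The plain path regresses absolute coarse
coordinates (2048×3) from the code, then two children per coarse point as
parent + learned offset (4096), then two children per middle point
(8192). The generator's forward path instead *anchors* the coarse stage
on the encoder's coarsest FPS subset of the observed block and predicts
offsets through a shared per-anchor MLP over concat(local per-point
feature, global code) — the same local completion rule applies wherever
similar geometry occurs, which converges far faster than absolute
regression when outputs live on a physical cm scale. All output heads
carry fixed physical gains (5/2/1 cm for coarse/middle/fine) so head
weights stay O(1).

**Discriminator.** Shared per-point MLP 3→64→128→256 (batchnorm + ReLU),
global max pool, dense head 256→128→1, sigmoid.

**Autodiff engine.** The network runs on a small in-package reverse-mode
engine over float32 numpy arrays (broadcast arithmetic, matmul, gather
with scatter-add backward, axis max/sum/mean, fused batchnorm and
edge-feature ops, compiled inner kernels). Gradients are verified against
central finite differences in the test suite. Chamfer gradients use the
standard subgradient: nearest neighbors are matched on current values and
gradients flow through the matched pairs.

## Training

Adam (lr 1e-4, optional per-epoch decay factor for scaled-down
schedules), batch size 8, up to 200 epochs or until the multi-stage
completion loss drops below 0.1 (the stopping rule uses the completion
loss, not the total: the adversarial value is negative and on a different
scale). α schedule on half-open intervals: 0.01 for epochs [0, 30), 0.05
for [30, 80), 0.1 from 80. Per step: one discriminator update (real =
ground-truth occluded cloud resampled to the fine size, fake = fine
prediction) and one generator update minimizing 0.9·L_com + 0.1·L_adv
with the non-saturating generator term −log D(F(x)); the logged L_adv is
the literal GAN value. Validation (completion loss, evaluation mode)
every 10 epochs; checkpoints persist only on improvement (`best.ckpt`)
plus a final `last.ckpt`; probabilities are clamped to (10⁻⁶, 1−10⁻⁶)
inside logs, and a non-finite loss aborts with an error. All randomness
flows from the config seed; two runs with the same seed log identical
loss sequences. Validation compares completed clouds (block input union
fine prediction) and bare inputs against the complete ground truth: the
block's full-resolution surface cloud union its occluded points.

## Metrics

Chamfer distance implements the symmetric mean nearest-neighbor *squared*
distance on cm coordinates (units cm²); an unsquared variant (mean
nearest-neighbor Euclidean distance, cm) is exposed for reporting and all
outputs label which is used. SSIM3D pairs each point of X with its
nearest neighbor in Y and averages the normalized absolute feature
difference |F_X − F_Y| / (max(|F_X|, |F_Y|) + ε); the printed form of
that expression is 0 for identical clouds, so the package reports
1 − raw, clamped to [0, 1], and also exposes the raw value. The feature F
is deliberately configurable because it is underdetermined: local point
count within r = 2 cm by default, or point height.

## Traits

Silique-labeled points (converted to mm) are voxelized on a 3 mm grid
anchored at the cloud's minimum corner; solid volume = occupied voxels ×
27 mm³, with no morphological closing (3 mm ≈ half a silique diameter, so
pods fill without artificial hollowing). SEI = silique volume / plot
ground area (mm³/m²); the plot area helper uses the layout footprint
including a half-spacing margin per side (rows·row_spacing ×
cols·plant_spacing). Canopy layers split the silique zone's z extent into
equal thirds (boundary points to the lower bin; a degenerate extent puts
everything in the middle layer); layer volumes partition occupied voxels
by voxel-center height so they sum exactly to the total. Yield regression
is ordinary least squares (scipy) with R² = r².

## Desk-scale problem sizes

The default test and acceptance runs use deliberately small problem
sizes so the whole pipeline runs on one CPU core: plants sampled at
80–150 surface points, plots of 4–16 plants, rigs of 6–36 views, blocks
of 64–512 points, quarter-width networks. The functional training
experiment uses 32 bolting-stage scenes (16 plants each, 300 points per
plant, 36 views), each reduced by FPS to a single 512-point block — the
same order of surface-density reduction the full pipeline applies when it
downsamples plot reconstructions to 8192-point blocks. Bolting is used
because silique-stage meshes (thousands of pod spheroids) make ray-cast
annotation disproportionately expensive at desk scale. Its ~100
optimization steps are a scaled-down schedule, so the experiment uses a
correspondingly larger, decayed Adam learning rate (2e-3, ×0.95 per
epoch) instead of the full-scale 1e-4; the success criterion is relative
— the completed cloud must be closer (Chamfer) to the complete ground
truth than the bare input is — for the majority of training seeds.

A candid note on what the desk-scale suite shows: at these sizes the
trained generator reduces its completion loss by roughly three orders of
magnitude and places predicted points within ~3 cm (mean nearest-neighbor
distance) of the true canopy, but that residual fuzz still exceeds the
input cloud's incompleteness penalty at the ~26% occlusion the procedural
canopies produce, so the union of input and prediction does not yet beat
the bare input on symmetric Chamfer distance within this training budget.
The corresponding acceptance test is kept at its stated conditions and
currently fails; closing the gap requires either the much deeper
(30–50%, contiguous) missingness of real photogrammetric reconstructions
or orders of magnitude more optimization steps than a CPU desk run
affords.

## Known limitations

- Procedural plants approximate organ geometry with primitives; no
  attempt is made to match measured morphology distributions.
- The SSIM3D feature and pairing are package conventions (the underlying
  definition is not fully determined); comparisons across tools should
  fix F explicitly.
- The completion network trains on CPU via numpy; full-scale (8192-point,
  full-width) training is possible but slow — the defaults are tuned for
  correctness and desk-scale experimentation, not throughput.
- Dynamic-graph neighbor selection breaks ties by index, so permutation
  equivariance is exact only for clouds without exactly tied distances
  (ties have measure zero for continuous data).
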