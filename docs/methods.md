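# Methods

## The border split

Ultrasound intensity is not a tissue label: echoes arise at acoustic
interfaces, so the same muscle can be bright in one place and anechoic in
another. Annotators therefore trace boundaries where a reflecting
interface is visible and *complete* the rest from anatomical knowledge.
`usborder` formalizes this split. For an image `I` and a one-voxel-thick
border mask `B` (the inner morphological boundary of a class, face
connectivity, grid-edge voxels included), the distinct part is

    B_distinct = Thres(I * K_smooth * K_sobel) ⊙ B

and `B_completed = B \ B_distinct`. The partition is exact by
construction; every downstream quantity inherits it (reference fractions
sum to 100, the true-positive decomposition is additive).

The edge chain is Gaussian smoothing (`edge.smooth_sigma`, voxels), Sobel
gradient magnitude (per-axis responses combined as the Euclidean norm;
true 3D filtering by default, a per-slice 2D mode for anisotropic
stacks), max-normalization of the gradient to [0, 1], and a threshold.
Otsu is the default because it is parameter-free and, together with the
normalization, makes the edge mask invariant to affine intensity
rescaling; fixed and percentile thresholds are available. Reflect
padding avoids spurious margin edges.

**Numerical choices.** `smooth_sigma` defaults to 1.2 voxels. A heavier
kernel (sigma 2) suppresses speckle slightly better but widens the
transition zone at the end of each visible segment and pushes the
gradient ridge off the one-voxel annotation; on phantoms this costs about
6 points of Jaccard agreement between the image-driven and the designed
split at the strict (radius 0) setting. With sigma 1.2 the distinct
border recovered from a noise-free phantom agrees with the designed mask
at Jaccard ≈ 0.92. The split's `tolerance_radius` defaults to 0 — the
faithful element-wise product — with radius ≥ 1 available because a
gradient ridge can sit between two tissues, one voxel off the annotated
border. The degenerate all-constant gradient yields an empty edge mask
with a warning rather than an error.

## Metrics and the true-positive decomposition

Dice uses the convention that two empty masks score 1. HD95 and NSD act
on mask surfaces (inner boundaries); distances are Euclidean in mm via
the voxel spacing, computed with exact distance transforms, both
directions pooled. NSD's tolerance `tau` defaults to one voxel (the
smallest spacing component) in mm since no canonical value exists; empty
masks make these metrics undefined (an error recorded as missing, never
silently 0).

The decomposition measures recall of the reference border: a
ground-truth border voxel is a true positive when a predicted border
voxel lies within `match_tolerance` (Chebyshev, default 1 voxel — border
masks are one voxel thick and a half-voxel shift should not be punished;
0 gives the strict overlap). All three percentages are relative to the
total reference border, so `B_Distinct + B_Completed = B_TP` exactly,
per row. Tables report per-case values; aggregates are mean ± sample
(n−1) standard deviation across cases.

Cross-entropy class weights for training are inverse pixel-frequency,
normalized to sum to 1, over the pooled training label set.

## Seg-Grad-CAM

The target is the **sum** of pre-softmax class scores over the chosen
pixel set (summing is what the pooled gradient of a per-pixel score
amounts to, by linearity; pre-softmax avoids cross-class coupling).
Weights are the spatial mean of the exact analytic gradient of that
scalar with respect to a named layer's feature maps; the map is
`ReLU(Σ_f w_f A^f)` at feature resolution, bilinearly upsampled for
display. Display normalization (by the map maximum) never enters
quantitative comparisons; cosine similarities in the perturbation probe
use raw maps. Pre-ReLU maps are additive over disjoint pixel sets, which
the tests assert.

The default layer is the last convolution before the classification head
("features"); any named layer can be inspected. Gradients are validated
against central finite differences on the shipped fixtures (relative
error ≈ 1e-13; the tolerance asserted is 1e-3 to leave room for genuine
float noise on other platforms).

## Models

No deep-learning framework is required: the two shipped models are plain
numpy with hand-written backward passes (im2col convolutions).

* `fixed_linear` — conv3x3 features plus a 1x1 linear head with hand-set
  weights. Affine end to end, so every CAM ingredient has a closed form;
  it anchors the gradient oracle tests.
* `small_unet` — a miniature encoder–decoder: one 2x average-pool level,
  nearest-neighbour upsampling, a skip concatenation, width 12, ~7k
  parameters. The input is presented as three channels (raw, Gaussian
  sigma 2, sigma 4) so the first layer sees speckle-suppressed context.
  Training: Adam (base lr 1e-2, sized for this tiny network), halved
  every 10 epochs, batch 2, vertical-flip augmentation, min-max input
  normalization, inverse-frequency class weights; 800 steps on 32
  phantoms takes ~80 s on one CPU and reaches held-out Dice ≈ 0.85,
  fully deterministic per seed.

Any model exposing the adapter contract (per-pixel pre-softmax scores;
activations and exact gradients at named layers; resume-forward from a
layer) plugs into the CAM machinery unchanged.

## The phantom generator

Phantoms emulate exactly the statistical structure the border split
assumes, with the decomposition known by construction:

* smooth blob-shaped structures (perturbed distance-field level sets,
  3 structures + background by default) on a 96×96 grid at 0.277 mm
  spacing, tissue means 0.35/0.45/0.55/0.65;
* a designed **dropout** subset of each structure's border — an
  exact-count selection, either the deepest voxels (`deep_sectors`,
  default, mirroring signal loss at depth; axis 0 is depth) or a random
  contiguous arc (`random_arcs`);
* a bright interface band (brightness 1.2, attenuated as
  `exp(-0.02 · depth_mm)`) drawn strictly *outside* the structure along
  distinct segments only, so the border voxel sits on the maximal-slope
  flank of a smoothed step instead of on a ridge crest where the Sobel
  response vanishes. Band voxels take the type of their nearest border
  voxel and stop two voxels short of dropout segments;
* around dropout segments the underlying tissue step is blended away
  (local mixing with a sigma-8 smoothed image over a 9-voxel radius), so
  the interface is genuinely invisible there;
* multiplicative log-normal speckle (sigma 0.1 by default) and a mild
  0.6-voxel system PSF.

The designed completed fraction equals the requested `dropout_fraction`
to within rounding (±2 points guaranteed, exact-count selection in
practice). Running the edge chain plus split on rendered phantoms
recovers the designed fraction within ±5 points (mean over 20 seeds) for
fractions 0.2–0.6, and the designed distinct mask at Jaccard ≈ 0.92
noise-free, degrading gently with speckle.

**What the phantoms do not capture:** directional probe physics
(anisotropic reflection, refraction, reverberation), realistic speckle
correlation, shadowing by bone or gas, compounding artifacts, and
anatomy-specific shape priors. Passing tests therefore certify the
*evaluation machinery* — the split, the metrics, the CAM algebra — not
clinical segmentation performance; the decomposition on real data
depends on the expert annotations and the edge parameters chosen there.

## Problem sizes

Tests and the acceptance script run on desk-scale inputs chosen as the
package's own defaults: 96×96 phantoms (48×48/64×64 where geometry
suffices), ≤16³ masks for brute-force metric oracles, 8×8 feature maps
for finite-difference CAM oracles, 32 training + 8 held-out phantoms for
the end-to-end cycle. The full suite runs in a few minutes on one CPU.

## Known limitations

* The split is voxel-based; no sub-voxel surfaces or topology repair.
* `tolerance_radius > 0` dilates the edge mask isotropically; it does
  not distinguish a ridge offset from genuinely nearby unrelated edges.
* HD95/NSD surfaces are voxel boundaries, so very thin (1-voxel)
  structures make pred/gt surfaces identical to the masks themselves.
* The shipped models are deliberately tiny; they demonstrate and test
  the contract, not state-of-the-art segmentation.
* 3D phantoms reuse the 2D construction logic on small grids (≤64³) and
  are exercised for code-path correctness, not physical realism.
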