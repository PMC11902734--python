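# Methods

## Problem and model

The package segments two object classes in RGB orchard imagery — fruit
(apple) and its stem — as pixel-level instances. Stems matter for
robotic harvesting but occupy a tiny fraction of the fruit's area, so
the design centres on parameter-efficient feature extraction plus
attention that preserves small-object signal through the neck.

The network is a single-stage anchor-free detector with a mask-prototype
segmentation head, following the YOLOv8-seg layout with two
substitutions:

**Ghost bottlenecks** replace the backbone's dense stride-2
convolutions. A ghost module computes a primary 1×1 convolution to
`c2/r` channels and generates the remaining `c2(r-1)/r` channels with a
k×k depthwise convolution of the primary output, concatenating both.
The bottleneck stacks two ghost modules around an optional stride-2
depthwise downsample and a squeeze-and-excitation (SE) gate, with a
depthwise + pointwise projection shortcut whenever shape changes. For a
3×3 dense convolution `c1 -> c2` the weight count is `9 c1 c2`; the
ghost module needs `c1 c2/r + 9 (r-1) c2/r`, strictly smaller for every
`r >= 2` (asserted over a configuration grid in the tests, and for the
assembled backbone at full scale).

**Global attention modules (GAM)** sit after the two finest neck fusion
stages (the stride-8 and stride-16 head inputs). Channel attention pools
the map (`GAP`), passes two 1×1 projections (SiLU between, sigmoid at
the end) and rescales channels; spatial attention passes the
channel-attended map through two wide convolutions (channel reduction
then restoration, sigmoid at the end) and rescales positions. With all
weights and biases zero both gates output sigmoid(0) = 0.5, so the
module scales its input by exactly 0.25 — a property the tests use as an
analytic anchor.

Activation conventions: every convolution is followed by batch
normalisation (eps 1e-3, running-stat momentum 0.03) and SiLU, except
(a) the final projections of SE/GAM branches, which carry a bias and end
in a sigmoid, (b) the shortcut's pointwise convolution (normalisation
only), (c) the SE reduction layer, which uses ReLU per the SE
convention, and (d) head output projections (bias, no norm, no
activation). The SE reduction uses ReLU while the GAM channel branch
uses SiLU; both reductions default to 4. The GAM spatial kernel defaults
to 7×7. The channel-attention branches carry no normalisation (they
operate on pooled vectors). The hidden width between a ghost
bottleneck's two ghost modules is `c2/2`. Ghost ratio `r = 2`, primary
1×1, cheap 3×3 depthwise. SE is active in the stride-2 bottlenecks
(all three backbone bottlenecks are stride 2); a switch enables or
disables it globally.

The layer graph: Conv(64,s2) → Conv(128,s2) → C2f×3 → Ghost(256,s2) →
C2f×6 → Ghost(512,s2) → C2f×6 → Ghost(1024,s2) → C2f×3 → SPPF(5);
top-down neck with upsample/concat and C2f×3 fusions, GAM after each of
the two finest fused maps; bottom-up path via stride-2 convolutions
re-concatenating the mid and coarse levels (the second one is stride 2
so its output aligns with the SPPF map for concatenation); the head
reads (GAM1 @ s8, GAM2 @ s16, final C2f @ s32). `width_multiple` /
`depth_multiple` scale the nominal channels/iterations; the **tiny**
preset (0.25 / 0.34) exists solely to make CPU-scale training practical
and is not the nominal configuration. Head branches use hidden width
`max(16, c/4)` per scale so the tiny preset's head scales down with its
backbone; the prototype head (32 prototypes) operates at stride-8
resolution.

## Training

Task-aligned assignment: each ground truth claims its top-10 cells by
alignment `score^0.5 * IoU^6` among cells whose centre lies in its
candidate window; contested cells go to the higher alignment. The
candidate window is the box dilated to at least one grid cell per side —
without this, boxes thinner than the stride-8 grid (stems are 2–6 px
wide) receive no candidates at all and the class is never learned.
Target scores are the per-ground-truth normalised alignments scaled by
the best IoU, and (as in the reference regime) are treated as constants
by the gradient.

Losses: CIoU on positive boxes (decoded differentiably from the softmax
expectation of 16-bin side distributions), BCE classification over all
cells against the soft targets, distribution focal loss (cross-entropy
against the two bins bracketing each true side distance; a target on
the final bin degenerates to one-term cross-entropy), and mask BCE on
sigmoid-combined prototypes, cropped to the ground-truth box and
normalised by its area. Weights 7.5 / 0.5 / 1.5 / 1.0. Ground-truth
prototype masks are rasterised 4× oversampled and pooled at 12.5%
coverage so sub-cell-width stems still produce non-empty targets.

The box head's output bias is initialised with a per-bin decay so the
untrained side-distance expectation is ~1.5 bins rather than the uniform
distribution's reg_max/2: untrained boxes are then compact, which gives
thin objects workable initial IoU in the aligned assignment instead of
a near-zero bootstrap signal. Class logits start at bias -4.6.

Optimiser: SGD, momentum 0.937, weight decay 5e-4 (kernels only), lr0
0.01 with 3-epoch linear warmup and cosine decay to 1% of lr0; nominal
schedule 500 epochs with early stopping at patience 100 on validation
loss; best-on-validation weights retained. Augmentations: 4-image
mosaic (disabled for the final 10% of epochs), horizontal flip, pixel
shifting with polygon adjustment, optional coarse-cutout dropout
(default off) — all label-consistent, with clipped-degenerate polygons
dropped. Batch size defaults to 8.

## Synthetic scenes

The generator emulates the statistical structure of fruit/stem imagery:
1–3 shaded elliptical apples (radius 12–30% of the frame, red/green/
yellow palette, radial shading, specular highlight, additive noise),
each with exactly one stem — a thick quadratic-Bezier curve, width 2–6
px, length 5–15% of the frame, attached at the apple's top boundary and
with probability 0.15 shifted partly behind its apple. Backgrounds
rotate among plain / vertical-gradient / low-frequency-texture / dark
modes (mirroring open-table, turntable-box and dark-chamber acquisition
styles), with a global illumination gain in [0.6, 1.4]. Ground truth is
exact by construction: apples are 48-gon polygonised ellipses; stems
are thick-curve outlines clipped against every apple ellipse, so
occluded stem parts are excluded from the label. Apples are placed
without mutual overlap (crowded scenes draw smaller radii; placement
restarts deterministically on the same RNG stream if a layout
dead-ends); scenes are a pure function of (config, seed), and dataset
scene *i* uses seed `seed + i`.

What the generator does **not** emulate: real textures, leaves and
branches, depth-of-field and motion blur, touching/overlapping fruit,
and real stem appearance diversity. Passing the learning check
therefore demonstrates that the architecture, losses, assignment and
optimisation interoperate and can fit fruit-plus-thin-stem structure —
not field performance on orchard photographs.

## Numerical and engineering choices

The network stack is implemented on numpy: a reverse-mode tape with
im2col+GEMM dense convolutions (the column buffer is reused by the
backward pass), shift-and-accumulate depthwise convolutions, argmax-
routed max-pool gradients (ties go to the first flat index), and batch
normalisation with the standard fused backward. Float32 throughout;
block outputs match float64 loop references to better than 1e-5
relative error at test sizes. Polygon rasterisation is an even-odd
scanline fill sampled at pixel centres (x = j + 0.5), making mask
contracts exactly checkable against a brute-force point-in-polygon
oracle. Image resizing is half-pixel-centre bilinear sampling with edge
clamping; boxes are half-open `[x_min, x_max)`; mask threshold is 0.5
with ">= is foreground", applied after upsampling. NMS is classwise
greedy with ties broken by lower candidate index. Evaluation uses
101-point interpolated AP (COCO convention — the printed-table
comparisons of other implementations may use different integrators),
greedy highest-IoU matching, confidence-sweep decoding at threshold
0.001 for AP (deployment prediction keeps the 0.25 default), per-class
max-F1 operating points for scalar precision/recall, mask IoU at original raster resolution, and an
unweighted per-class mean for the "All" row.

Desk-scale run sizes (used by the heavy test and `scripts/acceptance.py`):
200 training scenes at the generator's native 320 px, 40 held-out
scenes, tiny preset at 192-px network input with a 5×5 GAM spatial
kernel, batch 8, 30 epochs — chosen once as the package's CPU-scale
configuration (≈ 15 min on one core). At this input resolution stems
are ~1–4 px wide, which is the regime the dilated assignment window and
oversampled mask targets address.

## Known limitations

- Single-CPU numpy training is practical only at tiny scale; the full
  nominal network is assembled and shape/parameter-verified but not
  trained here.
- Stem mask AP at 192-px input is weak (stems span less than one
  prototype cell); stem *box* detection is the meaningful signal at
  this scale.
- Batch-norm running statistics make validation metrics noisy in the
  first epochs (eval-mode normalisation lags batch statistics).
- The evaluation's greedy matcher is the common approximation, not an
  optimal bipartite assignment; with overlapping ground truths it can
  differ from the optimum at threshold boundaries.
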