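# Methods

## Problem and model

`tomseg` segments tomato plant imagery into four classes — background/other
(0), stem (1), branch (2) and sucker (3) — from RGB-D input, with the sucker
(axillary shoot, the organ removed when pruning) as the detection target.
The model is a two-stage cascade of depthwise-separable convolutional
networks:

1. **Stage 1** is a small gate network (14,432 parameters): a strided 3×3
   convolution to 32 channels, three depthwise-separable blocks
   (32→64 stride 2, 64→96, 96→32), a 1×1 classifier and a ×4 bilinear
   upsample back to full resolution, followed by a per-pixel softmax.
   Its segmentation is *not* part of the final output; only its confidence
   map is used.
2. **Gating.** The per-pixel confidence is the maximum class probability
   ("Premax"). Pixels with confidence ≤ t1 (default 0.7) are *hard*;
   ties count as hard because a borderline pixel deserves the extra
   information path. Easy pixels are zeroed out of two auxiliary inputs.
3. **Stage 2** (666,328 parameters with the depth branch) receives the full
   RGB image (→12 channels), the easy-pixel-removed RGB image (→16) and the
   easy-pixel-removed mean-centered depth map (→4), concatenated to 32
   channels. A trunk of three stride-2 3×3 convolutions reaches 1/8
   resolution; then three inverted-bottleneck residual blocks (expansion
   6/5/4 at 64 channels), three multi-kernel feature blocks, a pyramid
   pooling module, a two-resolution skip fusion with the 1/4-resolution
   trunk feature, and a classify head (two depthwise-separable blocks,
   ×4 bilinear upsample, dropout 0.1, 1×1 conv to 4 classes).

Depth enters only at hard pixels, and only as *relative* depth: the grand
mean of the frame is subtracted (so the prediction is exactly invariant to a
constant camera offset) and the result is scaled to meters so its dynamic
range matches [0,1]-normalized RGB. The intended effect is disambiguation of
the crossing-stem case: a far stem passing behind a near stem–branch axil
looks like a sucker in RGB but sits on a different depth layer.

Two ablations are built by the same code: **Version 2** replaces the depth
branch's input with the masked RGB image (third input conv consumes 3
channels instead of 1, +72 weights); **Version 1** is the stage-2 structure
alone fed plain RGB in all three input branches, with no gating pass.

## Architecture arbitration

The block tables that describe this network leave several choices open, and
a few entries are mutually inconsistent (a group count of 26 on 64 channels;
a bottleneck chain ending at 96 channels feeding a block specified at 64; a
channel column that matches neither inputs nor outputs under any single
reading). `tomseg.blocks.ArchVariantFlags` enumerates every such reading —
bias and normalization placement, the first stage-1 layer, the meaning of
"DSConv" inside the feature blocks, the bottleneck chain, six skip-fusion
variants, where the pyramid pooling module taps the trunk, and upsampling
style — and `resolve_variant` arbitrates among all combinations against the
published trainable-parameter totals of the full network (680,760) and of
Version 2 (680,832).

Three combinations reproduce both totals exactly; all three require the
stage-1 entry layer to be a full convolution (any depthwise convolution on
the 3-channel input contributes an odd parameter count, while the published
totals are even) and the "collapsed" bottleneck chain (64,64,64), which is
also the only reading under which the feature-block group/channel rows are
divisible exactly as printed. The frozen default (`DEFAULT_FLAGS`) is the
member that keeps the stage-2 trunk as plain convolutions, reads the
feature-block branches as grouped convolutions with a pointwise mixing conv
wherever the branch is not already depthwise, folds the final 1×1 reduction
of the dilated feature block into the pyramid pooling module (input 256,
pool bins 1/2/3/6, concatenate, 1×1 to 96), and fuses the skip by projecting
the 96-channel trunk output to 64 channels, upsampling ×2 and adding it to
the 1/4-resolution trunk feature. Biases are off before normalization,
batch-norm affine terms on, and all upsampling is bilinear without corner
alignment. The dilation column of the dilated feature block reads 0/1/2;
rate 0 is undefined, so rates (1,2,3) are used (the alternative literal
reading (1,1,2) is kept behind a flag; parameter counts are unaffected).

Version 1's published total (690,596) exceeds Version 2's despite lacking
stage 1, which no reading reconciles; its count is reported as built
(666,400) and is not an anchor.

## Training protocol

Training runs twice over the data. Phase 1 optimizes stage 1 alone against
its own output. Phase 2 freezes stage 1 entirely — parameters, normalization
statistics and mode — and optimizes stage 2 against the final output, with
the hard-pixel gating recomputed per batch from the frozen stage 1. The loss
is unweighted per-pixel cross-entropy over the four classes (a class-weight
hook exists but is off by default). The optimizer is SGD with momentum 0.9
and no weight decay; batch size 12, 40 epochs, initial learning rate 0.025
multiplied by 0.997 after every optimizer step ("iteration" is taken as one
optimizer step, not one epoch). No pretrained weights are used. The dataset
splits 80/10/10 (train/validation/test) by a seeded uniform shuffle, and the
checkpoint with the best validation mean IOU is kept. All randomness flows
from a single integer seed; training is bit-deterministic for a given seed.

Augmentation (each op independently with probability 0.5): horizontal flip
and upscale-by-1.0–2.0-then-random-crop applied identically to RGB, depth
and label (nearest-neighbor for the integer maps); Gaussian blur (σ ∈
[0.5, 1.5]), per-channel additive noise (±10/255) and brightness (±20%)
applied to RGB only, since photometric changes leave the depth map valid.
Magnitudes are package choices.

## Numerical substrate

The networks run on a small reverse-mode autodiff engine over NumPy
(`tomseg.nn`): grouped/dilated/strided conv2d (with dedicated pointwise and
depthwise fast paths and an im2col path for general grouped kernels), batch
normalization, bilinear resampling and adaptive average pooling implemented
as separable linear operators (so their adjoints are exact transposes),
ReLU/ReLU6, dropout, transposed convolution, and a fused
softmax-cross-entropy. All activations are float32. Gradients of every
operator are tested against central finite differences. Bilinear
interpolation uses half-pixel centers (no corner alignment). Batch norm uses
ε = 1e-5 and momentum 0.1 for running statistics; inverted bottlenecks use
the clipped rectifier (ReLU6) internally and a linear projection, per the
mobile-architecture convention.

## Depth I/O

Depth is integer millimeters (the native unit of the targeted RGB-D camera
class). On disk, either a raw 16-bit single-channel PNG or the 24-bit
RGB-encoded PNG with `d = R + 256·G + 65536·B` — a bijection on [0, 2²⁴)
verified by property test; the encoded form is the canonical output. The
label palette (violet stems, pink branches, green suckers, black other) is
only a visualization; class semantics live in the index map.

## Synthetic scenes

The authors' farm dataset is not deposited, so the package ships a seeded
generator that emulates its statistical structure rather than its
appearance: thin elongated strokes (stems 8–14 px wide and near-vertical,
branches 5–10 px leaving stem nodes at 35–65° from vertical, suckers 4–8 px
wide and 20–60 px long rising inside the stem–branch axil), hard
non-anti-aliased class boundaries, strong class imbalance, and two depth
layers (near plant 500 mm, far plant 800 mm, background 1500 mm, Gaussian
noise sd 4 mm) with the far plant drawn first so a far stem can cross behind
a near axil — the misclassification trap the depth input addresses. RGB is
flat class-dependent greens/browns plus noise. Suckers that lose stem or
branch contact to occlusion are relabeled as background (unlabeled plant
matter also exists in the real data). Sucker probability per node defaults
to 0.7, putting the sucker class at a few percent of pixels on the default
480×640 canvas.

What passing tests on these scenes show: the architecture is assembled
correctly, gradients flow, the two-phase protocol optimizes what it claims
to, gating and depth fusion behave as specified, and the evaluation
procedure counts correctly. What they do not show: segmentation accuracy on
real greenhouse imagery — real leaves, fruit, lighting and depth-sensor
artifacts are all absent, and the published real-data scores (IOU 64.05,
80.2% sucker detection, 138 fps on a desktop GPU) are not reproducible
without the original dataset and hardware.

## Evaluation

Per-class IOU excludes classes absent from both maps; the dataset-level
aggregate sums intersections and unions per class across images before
dividing, then averages over occurring classes (a foreground-only mean is
also reported, since the published mean's class set is unstated). Sucker
counting: binarize class 3 in prediction and truth; drop predicted
8-connected components smaller than t = 160 px (ground truth is trusted and
never filtered); a true sucker counts as detected when its component
overlaps the filtered prediction in ≥ 1 px (elementwise mask sum reaching
2). A region of exactly t px survives the filter ("smaller than" is strict).
Detection % is per sucker, and undefined (reported as null, never 0) when
the set holds no true suckers. Connectivity defaults to 8, configurable
to 4. Throughput measurement is wall-clock frames/second after warm-up,
reported for information only — it is hardware-dependent.

## Problem sizes used by the test suite

Unit tests run on 48×64 single-plant scenes. The capacity check trains on
five 120×160 scenes: 150 stage-1 steps, then stage-2 steps with the training
mean IOU polled every 25 steps, stopping at 0.9 (≤ 500 steps in total across
both phases). Augmentation is disabled for this check — it measures
memorization capacity on the clean scenes; with stochastic augmentation the
same budget measures robustness to the transform distribution and plateaus
lower. Training canvases must have sides divisible by 8 (the trunk's
three ceil-halvings); prediction pads and crops internally, so any size is
accepted at inference.

## Known limitations

- The capacity and overfit runs characterize optimization on synthetic
  scenes, not accuracy on real plants.
- Version 1's width choices are underdetermined (see arbitration); its
  parameter count intentionally deviates from the published figure.
- The NumPy substrate is single-threaded BLAS-bound; throughput numbers are
  orders of magnitude below the published GPU figures and are excluded from
  any comparison.
- `fit` keeps the whole dataset and one best-state copy in memory; it is
  sized for hundreds of 480×640 frames, not millions.
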