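# Methods

This note documents the model, the numerical choices, the synthetic data
the package is validated on, and the limits of what those validations show.

## Detection model

The detector is a single-stage, anchor-free network: a ResNet34 backbone
(stem 7×7/2 + 3×3/2 max-pool; stages of 3/4/6/3 BasicBlocks at widths
64/128/256/512), a three-level feature pyramid at strides 8/16/32, an
optional progressive fusion neck, and a decoupled head.  Each head level
runs two parallel branches (classification, box regression) of two 3×3
conv+BN+ReLU layers and a final plain 1×1 convolution; box outputs are
left/top/right/bottom distances from the cell centre in stride units, made
non-negative with softplus.  Confidence is the per-class sigmoid
probability; there is no separate objectness branch, matching a head
description with exactly two branches.

### ABSM — adaptive background suppression

Placed on the residual branch of every BasicBlock, before the addition
(squeeze-excitation convention).  Stages:

1. depthwise 7×7 convolution, stride 2, compresses the map;
2. each of the C channels becomes one attention token embedded as its
   flattened compressed response; depthwise 7×7 convolutions produce
   q/k/v; 4-head scaled dot-product attention mixes the C×C channel
   structure (the token dimension splits across heads; if it is not
   divisible by the head count the module falls back to one head);
3. global average pooling and a channel softmax yield weights `w` with
   Σw = 1; the input is rescaled by `C·w`, so uniform weights are exactly
   the identity — raw softmax weights would shrink activations by ~1/C and
   destabilise early training;
4. channel-wise mean and max of the refined map form a 2-channel spatial
   statistic; mean-pooling it along width and height gives directional
   profiles, a shared 1-D convolution (kernel 3) maps each to one channel,
   and the coordinate gate is `sigmoid(p_h + p_w)` broadcast over the map;
5. a 1×1 convolution over the coordinate-gated statistic, through a
   sigmoid, gives a second gate; the output is the refined map times both
   gates.

Both gates lie in (0,1), so the module can only attenuate the refined map.
With every weight at zero the module reduces exactly to `x/4` (two sigmoid
gates at 1/2 each), a closed form pinned in the tests.  All projections are
bias-free precisely to keep that case exact.

### LMSM — lightweight multi-scale extraction

One instance after each backbone stage.  Branch 1: p×p local average
pooling (p = 2), global average pooling, a 1-D convolution (kernel 3)
along the channel axis, then broadcast restoration to the map size —
"anti-pooling" is read as broadcast rather than max-unpooling, since no
pooling switches exist to invert.  Branch 2: 1×1 reduction to an inner
width m, a four-way channel split with 3×3 convolutions at dilations
(1, 2, 3, 4) (spatial size preserved via padding = dilation), concat, and
1×1 restoration.  Fusion is `branch2 · sigmoid(branch1) + x`: the sigmoid
gate is a design choice (the fusion operator is otherwise unspecified), and
the identity residual guarantees gradient flow — zeroing branch 2 gives
exactly the identity, also test-pinned.

The inner width is `m = min(16, C/16)`, i.e. per-stage reductions
(16, 16, 16, 32).  This is the calibration knob that holds the module's
total cost at ~0.098 GFLOPs, a 0.13 % increase over the ABSM-augmented
backbone — the printed relative cost this block is designed around.  A
global reduction of 8 would cost 2.5× that.

### PFFM / WSAF — progressive fusion

`WSAF(F01, F02)`: the operand not defining the output geometry is
bilinearly resampled and projected (1×1) to the other's channels;
`F1 = W1·F01 + W2·aligned(F02)` with unconstrained scalars initialised to
1; a per-channel gate `g = sigmoid(GAP(F1))` forms `z = g·F1 + F1`; the
output is `z + MHSA(z) + DWConv5×5(z)`.  Choices worth recording:

* The attention is residual (`z + MHSA(z)`): a bare attention output would
  discard locality and break the zero-weight closed form (`1.5·F01` for
  zero-mean input), which the tests pin.
* Queries are all spatial tokens; keys/values are adaptively average-pooled
  to at most 441 tokens (a 21×21 grid).  The token budget is the knob that
  sets the neck's cost.
* The depthwise 5×5 convolution on `z` is a local positional-enhancement
  path (in the spirit of convolutional positional encodings in hybrid
  attention blocks): attention over pooled tokens is translation-blind, and
  the depthwise path restores fine locality at negligible parameter cost.
  It is counted in the FLOP budget.
* The five units have independent parameters; the inner `ab`/`bc` units are
  computed once and shared between the outer expressions, so gradients from
  all three outputs reach them (test-pinned).
* The middle output `B = WSAF(ab, bc)` is produced at stride 16: the unit
  aligns its first operand (`ab`, stride 32) to the geometry of the operand
  whose stride matches the middle head slot.  The outer units for `A` and
  `C` follow their first operands (strides 32 and 8).  This is an
  interpretation — the fusion recipe alone does not fix the resolution of
  the middle expression — chosen so the head receives exactly one input per
  stride.

### Head targets and loss

A cell is positive when its centre lies inside a ground-truth box and
within 2.5 stride units of the box centre per axis; among containing boxes
the smallest area wins.  The loss is binary cross-entropy over all class
logits plus `1 − CIoU` on positives, weighted 1 : 5, both divided by the
positive count (with no positives, the classification term is the mean over
cells, giving the closed form `−log 0.5` at zero logits).  The CIoU
aspect-ratio coefficient α is treated as a constant during
differentiation, as is conventional.  Anchor-free ltrb parameterisation,
the assignment rule and the loss weights are design choices of this
package; the protocol this work follows specifies no loss.

## Complexity accounting

House convention: 2 FLOPs per multiply-accumulate; convolutions (grouped:
divided by groups), linear/1×1 projections and attention score/apply
matmuls are counted; pooling, normalisation, activations and elementwise
arithmetic are not.  Under this convention the plain baseline at 640×640
lands at 72.9 GFLOPs.  A published closed-form complexity expression for
convolutional networks that this figure nominally instantiates is
dimensionally inconsistent as printed (its first term lacks the spatial
factor and squares the input channels); the implementation follows the
standard per-layer formula above instead.

Two independent routes compute the totals: an analytic shape-propagating
walker over the module tree (`licodet.flops`), and a runtime profiler that
records `2·M·N·K` for every GEMM actually executed.  They agree exactly
when shape inference is correct; the test suite requires agreement within
1 %.

Free architecture hyperparameters — head branch widths (96, 200, 256 per
scale), the ABSM compression stride (2) and q/k/v kernel (7), the LMSM
inner-width rule, and the WSAF token budget (441) plus positional
convolution — were fixed by calibrating the analytic totals of the four
ablation presets against their reference complexity budgets
(72.9 / 75.6 / 75.7 / 83.1 GFLOPs), before any training experiments.  They
are architecture constants of this package, not tuning dials; the
calibration is deterministic arithmetic, independent of data, seeds or
hardware.  Notably, a compression stride of 4 in ABSM cannot reach the
module's 2.7-GFLOP budget under any q/k/v kernel (it saturates near
0.7 GFLOPs), which is why stride 2 is the default here.

## Training

Defaults mirror the reference protocol: 640×640 inputs, 200 epochs, batch
8, SGD (lr 0.001, momentum 0.937, weight decay 0.0005), seed 0, early
stopping on validation mAP50 with patience 50, best checkpoint kept.  The
learning rate is constant by default (only the initial rate is specified);
cosine decay is a flag.  Additions this package makes for numerical
robustness on its own stack: global gradient-norm clipping at 10 (the
attention-heavy full model diverges without it at aggressive learning
rates), and a non-finite-loss abort with diagnostics.  No warmup, no
mosaic/mixup — augmentation is exactly the four operators of the data
pipeline (mirror, k·90° rotation, brightness, translation).

`smoke_overfit` is a capability check, not the training recipe: it overfits
a handful of easy synthetic scenes (large unoccluded plants) at reduced
input size and reports train-set mAP50.  It uses Adam (lr 2e-3) with the
same clipping, because on this numpy stack every optimisation step is
expensive and Adam reaches the overfit criterion in several times fewer
steps than SGD; the trainer proper keeps SGD.

All computation is float32 numpy; convolutions run as im2col + BLAS GEMM,
and the im2col buffers are rebuilt during the backward pass rather than
cached, which bounds peak training memory (full model, batch 8 at 256×256)
below 2 GB.

## Evaluation

Greedy one-to-one matching per class in descending score order (highest-IoU
unmatched ground truth at or above the threshold).  Conventions, pinned in
tests: precision is defined as 1 when nothing was predicted; recall as 0
when nothing was there to find.  AP is the all-points interpolated area
under the precision envelope; mAP50-95 averages thresholds 0.50–0.95 in
steps of 0.05; classes absent from the ground truth are excluded from the
mean.  The AP implementation is verified against a brute-force oracle that
re-matches from scratch at every score cut.  F1–confidence and
precision–recall curves and Grad-CAM overlays (gradient-weighted, ReLU,
min–max normalised, bilinearly upsampled) serve as diagnostics.

## Synthetic scenes

The generator emulates the statistical structure of the field imagery this
kind of detector faces: three visually similar plant classes distinguished
only by (hue band, leaf count, leaf aspect) triplets; weed distractors
whose hues overlap all class bands (hard negatives); low-frequency brownish
background with speckle; log-uniform plant radii (12–220 px at 640,
"small" through "large"); and partial occlusion by weed blobs drawn across
plant edges.  A plant is labelled only if ≥ 25 % of its rendered area stays
visible — deliberately the same threshold as the tiler's box-keep rule.
Boxes are tight around visible pixels.  Scenes are deterministic functions
of `(seed, index)`, so any single scene regenerates without replaying the
dataset.

What the generator does **not** model: photorealistic texture, shadows and
illumination geometry, spectral/radiometric sensor response,
geo-referencing, plant phenology.  Passing tests on these scenes therefore
demonstrates that the pipeline, architecture, optimisation and metrics are
correct and that the model can learn fine-grained colour/shape
discrimination — not that field-imagery accuracy figures are reproduced.
Those require the original (undeposited) UAV dataset and GPU-scale
training, and are explicitly out of scope.

## Problem sizes used in the checks

The package's own validation runs at deliberately small scale so the whole
suite executes on one CPU core: module unit tests use 8–32 channels and
≤ 12×12 maps; backbone shape/finiteness checks run at 64–128 px; the
analytic-vs-profiled FLOP cross-check runs the baseline at 320 px (the
analytic totals themselves are computed at the native 640); the capability
check trains at 96–256 px on 4–20 scenes.  These sizes are the package's
choices for its test tier; the library itself has no input-size assumption
beyond divisibility by 32.

## Known limitations

* Throughput: a numpy/BLAS forward pass of the full model at 640² is a few
  seconds; GPU-scale experiments (200-epoch runs on ~10k images) are out of
  reach of this stack by design — the package targets correctness,
  reproducibility and architecture accounting, not speed.
* BatchNorm statistics are computed in training mode per batch; very small
  batches (1–2) make the running estimates noisy, which mildly affects
  eval-mode metrics early in training.
* The bilinear resampling in WSAF uses the half-pixel (align_corners=False)
  convention; mixing conventions with external feature maps would introduce
  sub-pixel offsets.
* Multi-device training, mixed precision, model compression and deployment
  export are non-goals.
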