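# Methods

## The reduction model

A block-based CNN is modeled as a composition of stages, each repeating
a block L times over tensors of shape ⟨H, W, C⟩. Compound reduction
rescales the three axes together:

    repeats  L → round(L · α^−φ)
    widths   C → round(C · β^−φ)
    input    H, W → round(H · γ^−φ), round(W · γ^−φ)

with α, β, γ > 1 tied by α·β²·γ² ≈ 2. Because convolutional cost is
linear in depth and quadratic in both width and resolution, the
continuous cost ratio per unit of φ is exactly (α·β²·γ²)^−1; with the
default coefficients (1.2, 1.1, 1.15) that is 1.9203 — close to, but
deliberately not exactly, the idealized 2×. The constraint check is
therefore advisory (tolerance ±0.1 around 2) rather than a rejection.

Only stages flagged depth-scalable lose repeats; stems, downsampling
entry blocks, reduction transitions and heads always survive (every
rescaled count is clamped at 1), so a reduced network keeps the same
number of spatial downsamplings as its parent and its minimum input side
is unchanged. Widths inside a block are stored as exact rational ratios
of the stage base width: the base is rounded once and per-layer widths
are recomputed from the ratios, which is what keeps the 1:1:4 bottleneck
expansion exact under scaling (base 256 at φ = 2 → 212, expansion
→ 848, not round(1024·β^−2) = 846).

**Rounding.** All integer rescaling uses round-half-to-even. This is the
only rule consistent with the full set of published reduced-architecture
cells we reproduce (3·1.2^−1 = 2.5 must go *down* to 2 while 58.18 → 58,
105.79 → 106, 232.73 → 233 and 384.66 → 385 round to nearest);
round-half-up would break the tie cell. Products are quantized to 1e−9
before rounding so binary float error cannot flip an exact tie. One
consequence: 240·1.15^−3 = 157.8 gives 158 (one published table prints
157, another 158 for the same quantity; the arithmetic supports 158).

The exponent φ is accepted as any non-negative real, though the studied
range is the integers 1–6; above φ = 3 the transform warns, because a
ResNet-style network collapses toward single-repeat stages and stops
resembling its parent.

**Input-reduction (IR) baseline.** The same γ^−φ applied to the input
side only, architecture untouched. It exists as the natural control:
parameters are exactly invariant under IR, FLOPs fall roughly as r².

**Budget-driven selection.** Given a FLOPs budget, the smallest integer
φ ≤ 6 whose compound reduction fits is chosen by direct enumeration of
the cost model; an unattainable budget fails loudly, quoting the cost at
φ = 6.

## Cost accounting

FLOPs count two operations per multiply-accumulate over convolutional
and dense layers only:

    F_conv  = 2 · C_in · K_h · K_w · H_out · W_out · C_out
    F_dense = 2 · N_in · N_out

Batch normalization, pooling, activations, and shortcut additions
contribute zero FLOPs, and no bias-addition term is counted. Parameters
count every stored scalar: conv kernels (plus bias where the layer has
one), batchnorm scale/shift/moving-mean/moving-variance (4 per channel),
dense weights plus bias. "Same" padding uses ceiling division for output
extents and "valid" uses floor((n−k)/s)+1, so shapes are defined for the
odd input sides the reduction produces (209, 181, 157, …). GFLOPs are
reported as total/10⁹ rounded half-up to two decimals.

## Template conventions

**ResNet-50 V2.** Pre-activation bottlenecks; stem 7×7/2 conv (64
filters, bias) + 3×3/2 max pool; stages at base widths 64/128/256/512
with repeats 3/4/6/3; head is batchnorm + ReLU + global average pool +
dense. Within a block the two inner convolutions are bias-free (their
batchnorms absorb the shift) while the expanding 1×1 and the projection
carry biases. This mixed-bias convention plus 4-parameter batchnorm is
what reproduces the 23,568,898-parameter total for the 2-class network
exactly; an all-bias or no-bias convention does not. Downsampling sits
in the *first* block of stages 2–4, with the stride on the 3×3 conv and
on the projection shortcut. The alternative (downsampling in the last
block of stages 1–3, as one popular implementation does) stores the same
parameters but spends ~15% fewer FLOPs at 240×240; the entry-block
convention is the one whose totals (9.61 GFLOPs at 240; 5.14/2.95/1.53
at φ = 1/2/3; ratio 3.25) match the published cost profile of this
architecture family to well under 1%, and it also matches the expected
stage output sides 60/30/15/8 at a 240 input.

**Inception template.** The built-in "inceptionv4" template is the
*residual* Inception topology (Inception-ResNet-v2): a six-conv stem
with a mixed block producing a 320-channel carrier, then 10× block35,
reduction, 20× block17, reduction, 10× block8 at carrier widths
320/1088/2080, a 1×1 conv to 1536 features, global pooling and a dense
head. Strided convolutions and pools use valid padding, as in the
reference implementation. This variant — often shipped as "Inception V4"
by Keras-based pathology pipelines — is the one whose cost profile this
package is calibrated against: 15.48 GFLOPs at 240×240 and 245
parameterized (conv + dense) layers, with depth scaling of the
(10, 20, 10) repeats reproducing the published reduced layer counts at
φ = 1 and 2 exactly. The non-residual Inception V4 of the original
architecture paper has ~150 parameterized layers and 14.51 GFLOPs at
240 and is *not* what those figures describe. Each residual block's
closing 1×1 projection takes its width from the residual carrier at
build time, so the blocks stay valid under any width scaling of the
surrounding stages; the damping factors (0.17/0.10/0.20) affect only
training dynamics, not cost.

## Runtime backend

`nar.runtime` is a small pure-NumPy engine: NHWC tensors, im2col
convolutions, batchnorm (momentum 0.99, ε 1e−3), max/average pooling,
residual blocks, softmax cross-entropy. Training follows the standard
protocol for this task: Adam (β₁ 0.9, β₂ 0.999, ε 1e−7), learning rate
5e−4, weight decay 5e−4, batch size 32, 50 epochs by default. Weight
decay is implemented as *decoupled* (AdamW-style) decay on conv/dense
kernels only — "weight decay with Adam" underdetermines the coupling,
and the decoupled form is the one with well-understood behavior. Batch
size and augmentation are not part of the protocol's published surface;
the defaults are 32 and none, both configurable. He-normal
initialization; all randomness flows through one seeded generator, and
single-threaded NumPy makes runs bit-reproducible per seed.

The backend's contract with the cost model is parameter equality:
`materialize(net).param_count() == count_params(net)` for every valid
spec, verified in the tests for both templates and all reduced variants.
Gradients are verified against central finite differences.

Patch resizing (dataset loading and slide tiling alike) is bilinear,
with intensities scaled to [−1, 1].

## TIL mapping

Slides are tiled into non-overlapping patches of fixed physical size
(50×50 µm; side_px = round(50/mpp), i.e. 200 px at 0.25 mpp, 100 px at
0.5 mpp), row-major from the top-left with 0-based half-open pixel
boxes; trailing partial patches are dropped so every patch covers
exactly the nominal area. No overlap/stride option is provided — the
workflow this models is a plain partition. Consequently the map shape
depends only on the slide's physical extent, and the number of patches a
model processes is independent of its input resolution. Scores ≥
threshold (default 0.5, configurable) are TIL-positive; maps round-trip
losslessly through CSV and are rendered as red dots on a blue background.
Pyramidal WSI formats are out of scope; any raster image plus an mpp
value works.

## Synthetic task

The generator emulates the binary TIL task: pink eosin-like tissue
texture with per-patch brightness jitter (σ 7 intensity levels), smooth
mottling and fine grain; dark basophilic nuclei as soft-edged ellipses
(semi-axes ~2–4% of the patch side). Positive patches carry ≥ 20 nuclei
(20 + Poisson(9)), negative patches at most 2. Matched seeds share the
background texture, so a positive patch is always slightly darker than
its matched negative — but across patches the brightness jitter is of
the same order as the mean shift the nuclei cause, so the *reliable*
class signal is nucleus density at a few-pixel scale. That makes the
task resolution-sensitive by construction: downsampling below the
nucleus scale removes the signal gradually, which is what lets the
input-reduction experiments show a graceful AUC decline (measured at
5 epochs × 3 seeds on 200/100 train/test patches: mean AUC 1.000 at
48 px, 0.993 at 21, 0.875 at 12, 0.798 at 8) rather than a cliff or
nothing.

What the synthetic task does *not* model: stain variation, tissue
morphology, focus artifacts, class imbalance across slides, annotation
noise. Passing the end-to-end checks shows the pipeline and the learner
are sound, not that any architecture would reach a particular AUC on
real H&E slides.

Slide images are composed from the same patch generator on the standard
grid (independent Bernoulli labels at a configurable positive fraction),
so the ground-truth grid matches the tiling by construction.

## Problem sizes

The test suite and the acceptance script run everything at desk scale by
choice: cost accounting and reduction arithmetic use the full 240-px
templates (they are analytic and instant); training checks use the
3-conv toy network at ≤ 48 px on 200/100 synthetic patches for 5 epochs,
which is where the task is comfortably learnable and runs are seconds
each. Parameter-contract checks materialize the full templates (the
count is independent of input side, so small sides are used for speed).

## Known limitations

* The memory bound of the original formulation is represented in
  `ReductionRequest` but only parameter count is modeled, not activation
  memory or wall-clock throughput.
* Scaling *up* (φ < 0) and the accuracy-guided grid search that produced
  the default coefficients are out of scope; coefficients are taken as
  configuration.
* Published layer-count columns ("param. layers", "# of layers") follow
  no single counting convention we could reproduce and are not targets.
* The NumPy backend is CPU-bound and single-threaded; training the full
  ResNet at 240 px is possible but not practical — that is what the
  reduction is for.
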