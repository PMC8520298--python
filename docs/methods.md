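# Methods

## Problem and model

The package segments the liver in axial CT slices: given a
Hounsfield-unit image, predict a per-pixel foreground probability and
threshold it into a binary mask. The model is an encoder–decoder
("U-shaped") convolutional network with four bespoke components:

**MSRB (multi-scale residual block).** Replaces the U-Net double-conv
stage. Two parallel branches — one 3×3 convolution, and two serial 3×3
convolutions that cover a 5×5 receptive field at 18C² instead of 25C²
weights — are concatenated and fused by a 1×1 convolution; a
1×1-projected residual of the input is added, and DropBlock is applied
last. Branches run at the output width, since the block stands in for
the stage's `in→out, out→out` convolution pair. The residual projection
is always a 1×1 convolution, even when channel counts already match.

**MSAM (multi-scale attention module).** Max-pools the input at scales
2, 4 and 8; fuses the pyramid coarse-to-fine (bilinear ×2 upsample, 3×3
conv, add); then a 3×3 conv, ×2 upsample, 1×1 conv and sigmoid produce
an attention map with the input's full (H, W, C) shape, which rescales
the input elementwise. Because the gate is sigmoid-valued the block is
contractive: |output| ≤ |input| elementwise. No batch-norm sits between
the final 1×1 convolution and the sigmoid. All internal convolutions
keep the input channel count; the figure-level contract leaves internal
widths open, and keeping C avoids a second width hyperparameter.

**AASPP (attention atrous spatial pyramid pooling).** Four parallel
branches — a 1×1 convolution and 3×3 dilated convolutions at rates 2, 4
and 8 — each gated by an MSAM, concatenated and fused by a 1×1
convolution. Each branch emits `out_channels` (the branch width is not
pinned by the architecture diagram; emitting the fused width keeps the
module symmetric). The rate-8 branch's effective receptive field is
17×17, verified by impulse-response probing in the tests.

**RASM (residual attention skip module).** Replaces the plain skip
connection. The decoder feature map (half resolution) is bilinearly
upsampled, concatenated with the encoder skip, refined by two MSRBs and
an MSAM, and summed with 1×1-projected residuals of both inputs.

The full network: `depth` encoder stages of MSRB + 2×2 max-pool with
filters doubling per stage, an AASPP bridge at the deepest resolution
(output width = deepest encoder width), `depth` RASM decoder stages
each consuming the matching encoder skip with widths halving per stage,
and a 1×1 convolution + sigmoid head emitting one foreground channel.
A single sigmoid channel (rather than a two-channel softmax) follows
the output-head description; the complementary background probability
is `1 − p`. Ablation flags replace MSRB with a plain double 3×3 conv,
AASPP with identity, and RASM with upsample + concat + double conv,
recovering a vanilla U-Net when all are off.

Every convolution is followed by batch normalization and ReLU, except
sigmoid-producing convolutions (the MSAM gate and the output head).
All convolutions use "same" zero padding; every figure-level shape
contract requires spatial preservation. Down-sampling is 2×2
max-pooling; pooling at scale k means kernel k, stride k, no padding,
which is why MSAM-bearing paths require spatial dimensions divisible
by 8 (the constructor rejects incompatible sizes rather than silently
padding). Bilinear resizing uses half-pixel (align-corners = false)
semantics, so constant maps resize to the same constant. Weights use He
fan-in normal initialization, seeded through the model config.

## Loss and metrics

Training minimizes `L = α·L_bce + β·L_dice` with α = 0.5, β = 1.0.
`L_bce` is the pixel-mean binary cross-entropy with probabilities
clamped to [1e−7, 1−1e−7]; `L_dice = 1 − 2Σpᵢyᵢ/(Σyᵢ+Σpᵢ)` is soft (no
binarization of p) with a 1e−6 smoothing term guarding the empty-empty
case. Loss is averaged per batch; the reduction convention is fixed and
documented here because results depend on it only through gradient
scale.

Evaluation binarizes at the strict threshold p > 0.5 and computes
DSC = 2|G∩P|/(|G|+|P|), IOU = |G∩P|/|G∪P|, precision = |G∩P|/|P| and
recall = |G∩P|/|G| per case, aggregated as mean ± standard deviation.
Per-case metrics pool all slices of a case before computing ratios
("per-volume", the default); a per-slice mode averages slice-level
metrics within the case instead. Empty-denominator convention: both
masks empty → 1.0 (a correct prediction of "nothing"); only the
denominator mask empty → 0.0.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−7) at initial learning rate 0.001,
batch size 6, at most 300 epochs. Validation loss is monitored with
min-delta 1e−4: 8 epochs without improvement halve the learning rate
(the plateau wait counter restarts after a reduction, so the next
halving needs another 8 flat epochs); 20 epochs without improvement
stop training; the best-on-validation weights are restored at the end.
The early-stop counter resets only on improvement. Inference can
average flip test-time augmentation (identity, horizontal, vertical,
both), inverse-mapping each probability map before the pixelwise mean.

## Numerical engine

No deep-learning framework is used: the package carries a compact
reverse-mode autodiff engine over numpy NHWC arrays
(`msaunet.autograd`). Convolution is im2col + one GEMM per layer (with
a pointwise fast path for 1×1 kernels); max-pool splits gradients
evenly across ties (a valid subgradient; ties are measure-zero on real
data); bilinear resizing is a separable pair of row-stochastic
interpolation matrices whose transposes give the exact adjoint; batch
normalization uses batch statistics in training (momentum 0.9 running
buffers, ε = 1e−5) and the running buffers in inference. Sigmoid
outputs are kept strictly inside (0, 1) at working precision so
saturated logits cannot round onto the closed endpoints. DropBlock
(default rate 0.1, block size 7 — the citation's common setting, as the
architecture source gives no values) zeroes contiguous squares seeded
at a rate that matches the target drop fraction, rescales survivors,
and shares its mask across channels; it is active only in training
mode. Default parameter dtype is float32; constructors accept float64,
which the finite-difference gradient tests use. Backpropagated
gradients agree with central differences to ~1e−8 relative error in
float64.

## Synthetic phantoms

The phantom generator emulates abdominal CT slice structure at desk
scale: one smooth organ blob (a random ellipse modulated by radial
harmonics at orders 2, 3 and 5) filled at 60 ± 10 HU (liver-like
parenchyma), over air (−1000), fat (−100), muscle (40) and bone (400)
background regions, with 15 HU Gaussian noise; HU are rounded to
integers as in real CT and clamped to [−1000, 1000]. Blob area is kept
within 5–40% of the image (axes are rescaled toward the feasible band,
erroring if infeasible) and area/centroid drift smoothly across the
slices of a case. Masks are exact blob interiors and simply connected.
Storage is lossless: uint16 PNG of HU + 1024, uint8 masks, with a
manifest CSV carrying the case-level 8:1:1 split.

What the phantoms do **not** model: organ texture, partial-volume
boundary blur, scanner artifacts, anatomical shape priors, tumors and
vessels. Tests passing on phantoms therefore demonstrate that the
architecture, losses, schedule and plumbing are correct and that the
network can learn smooth-blob segmentation — not that it reaches
clinical-grade accuracy on real CT, which requires the real request-
based datasets and GPU-scale training of the 512×512 configuration.

## Problem sizes used in tests

The test and acceptance runs use desk-scale configurations chosen to
exercise every code path on one CPU: depth 2, base 8 filters, 64×64
phantoms for convergence checks (the overfit run reaches training
DSC ≥ 0.95 well within 300 full-batch steps at lr 1e−3); 8×8 inputs
with float64 weights for finite-difference gradient checks; 10 cases ×
8 slices for the end-to-end pipeline. The default model configuration
(depth 4, base 64, 512×512) builds and predicts but is not trained in
the test suite.

## Known limitations

- Single-channel 2-D slices only; volumes are processed slice-wise.
- The engine is single-threaded numpy: fine at desk scale, not suited
  to training the 512×512 / depth-4 configuration.
- Reproducibility is exact for fixed seeds on a given platform; BLAS
  reduction order may introduce sub-1e−6 cross-platform differences.
- Whether the original evaluation pooled slices per volume or averaged
  per slice is ambiguous; both modes are provided (default per-volume).
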