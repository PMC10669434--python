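# Methods

## The model

`msrn` implements a family of lightweight convolutional networks for
multi-label classification of retinal OCT B-scans over four outputs
{AMD, ERM, ME, Normal}, plus a two-branch multi-scale variant.

**SRN (sparse residual network).** Six convolutional blocks with channel
plan 32/32/64/128/256/512. The stem is a single 7×7 convolution; every
other layer is 3×3 — the design principle is kernel factorization:
a 5×5 convolution is replaced by two stacked 3×3 convolutions with the
same receptive field, cutting per-unit parameters by 18/25 and
per-position multiply–accumulates from 25 to 18 (`substitute_kernels`
applies such rules in both directions). Each block ends with a 2×2
stride-2 max-pool (floor mode), and global average pooling produces a
512-vector fed to a C-way linear head. Depth variants differ only in
per-block layer counts — 8-layer (1,2,2,1,1,1), 10-layer (1,3,2,2,1,1),
12-layer (1,3,3,2,2,1). With residual learning on, each non-stem block
adds a skip from its input to its last convolution's output, before the
final ReLU and the pool; the skip is the identity when channels are
unchanged and a biased 1×1 projection at the four channel transitions.
There are no normalization layers, and every convolution and the head
carry biases. These conventions give exact learnable-parameter counts
1,804,932 / 1,961,764 / 2,588,772 for the three depths, 2,413,732 for the
12-layer plain network, and 5,177,540 for the two-branch model — the
combination of choices is pinned down by requiring all five printed
roundings (1.80/1.96/2.59/2.41/5.18 M) simultaneously.

**MS-SRN (multi-scale learning).** Two (or more) SRN trunks with
*independent* weights, one per input scale (default a 448 px local branch
and a 224 px global branch), their pooled 512-vectors concatenated and
classified by a single fully connected layer. Rationale: ME lesions are
coarse homogeneous cavities visible at low resolution, while ERM is a
thin membrane that survives only mild downsampling, so branches at
different scales carry complementary evidence.

**Loss.** Class-averaged binary cross-entropy on sigmoid outputs,
`L(p,y) = −(1/C) Σᵢ yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)`, mean-reduced over the
batch. Probabilities are clamped to [1e−7, 1−1e−7] before logarithms so
the loss is finite; the logit gradient is the exact unclamped `(p−y)/NC`.

**Metrics.** Per class, Acc/Sen/Spe from TP/TN/FP/FN; micro-averages pool
the counts across the four classes first. Undefined ratios
(zero denominator) are reported as absent, never as 0 or 1. Patient-level
accuracy is exact-match accuracy: a scan counts only if its entire 4-bit
prediction equals the truth; an optional patient grouping counts a
patient correct only when all their frames match. Across-seed comparisons
use a two-sided equal-variance two-sample Student t-test, significant at
p ≤ 0.05 (both groups constant and equal gives t = 0, p = 1 by
convention). Binarization threshold is 0.5 on sigmoid outputs.

## The network core

No deep-learning framework is used: `msrn.nn` is a compact float32
NumPy implementation of exactly the layers the SRN needs. Convolutions
are stride-1, zero-padded to 'same' size and evaluated as one GEMM per
layer via an im2col lowering; the input gradient is computed as the
correlation of the padded output gradient with spatially flipped,
transposed kernels (again a single GEMM). Max-pool backward routes
gradients through stored argmax indices (first-index tie-break).
The optimizer is SGD with classical momentum and L2 weight decay:
`v ← μv + (g + λw); w ← w − ηv`. Backpropagation is verified end-to-end
against float64 central finite differences in the test suite.

**Initialization.** Kaiming fan-in normal (std √(2/fan_in)) for all
weights, zero biases, all draws from one seeded generator so builds are
bit-reproducible. The last convolution of every residual block is
initialized to zero, so each block starts as the (projected) identity.
Without normalization layers this keeps the activation scale flat with
depth (plain Kaiming everywhere produced initial logits of ±18 and a
long plateau at the label-marginal solution); it changes no parameter
count and is standard practice for norm-free residual training.

## Training protocol

Defaults mirror the reference protocol: batch 64, learning rate 0.003,
200 epochs, momentum 0.9, weight decay 1e−4, an 80/20 train/test split,
five seeds reported as mean ± std (2 decimals, percent scale). The split
is stratified by exact label combination with largest-remainder
apportionment, so every combination's test share is within one record of
20%; the unit is the image by default (patient-level grouping available —
image-level splitting of per-patient frame blocks is leakage-prone and
the safe option is exposed). Augmentation is random rotation within ±10°
(magnitude unspecified upstream; small anatomical tilt) and independent
horizontal/vertical flips at probability 0.5 each. Images are read as
grayscale, scaled to [0,1] (no mean/std normalization), bilinearly
resized per branch, and replicated to 3 channels (the stem's 7·7·3·32
weight count forces 3 input channels). Inputs may have any even side
≥ 64; floor-mode pooling handles sides that are not multiples of 64
(224 → 3×3 before global pooling). The best-micro-accuracy checkpoint is
retained; a non-finite loss aborts with a diagnostic.

## The phantom generator

Real training data for this task (≈33k labeled B-scans) is private, so
`msrn.phantom` renders seeded synthetic B-scans: a curved four-layer
bright band (NFL/inner/outer/RPE intensities 0.85/0.55/0.38/0.95) over a
0.05 background, multiplied by smoothed unit-mean gamma speckle
(contrast 0.35, grain 1.2 px). Lesions are drawn independently per class
with marginals (p_amd, p_erm, p_me) = (0.22, 0.28, 0.11), matching the
reference prevalences (7273/9272/3597 of 32,960), so multi-disease
co-occurrence arises naturally; Normal is the explicit fourth label.
AMD = 1–3 Gaussian drusen domes (height 14–38 px at the native 512 side)
lifting the RPE with deposit material beneath; ERM = a 1–3 px bright
membrane floating 2–10 px above the surface across ≥30% of the width;
ME = 1–3 dark elliptical cavities inside the band. Geometry scales
proportionally with image side. Ground-truth bounding boxes are stored
per lesion, and labels are re-derivable from them by construction.

The membrane's 1–3 px thickness is the scale knob: after resizing to a
coarse branch it survives only as a faint halo, while at a fine branch it
is a distinct line — giving multi-scale fusion a mechanism to act on.

What the phantom does *not* model: A-scan optics, shadowing and
attenuation below lesions, vendor post-processing, motion artifacts,
inter-device appearance. Defaults are deliberately separable (high lesion
contrast, moderate speckle), so a small network learns them quickly at
desk scale; difficulty knobs (speckle contrast, lesion sizes/levels) are
exposed. Passing the learning checks therefore demonstrates that the
pipeline — generator, model, loss, optimizer, metrics — is correct and
trainable, not that the architecture reaches any particular accuracy on
clinical OCT.

## Grad-CAM

For class c, the gradient of logit c w.r.t. a block's pre-pool activation
map is spatially averaged into channel weights, the weighted channel sum
is rectified, bilinearly upsampled to the input size and max-normalized
(all-zero maps stay zero). The default target is the last block's
pre-pool map — 7×7 at a 224 input. For multi-branch models each branch's
map is computed against the shared fused logit. After max-normalization
the map is invariant to positive rescaling of the class's head weights.

## Problem sizes used by the test suite

The full protocol (hundreds of epochs, hundreds of thousands of images ×
steps) is a GPU-scale undertaking; the suite instead runs statistically
meaningful scaled versions, chosen once as desk-scale conditions:

* Learning check: SRN-8, 600 phantoms rendered at 128 px and resized to a
  single 64 px branch, batch 16, lr 0.015, 16 epochs, no augmentation,
  3 seeds, test micro-accuracy ≥ 0.85 per seed. At ~500 optimization
  steps the larger batch/smaller rate of the full protocol has not left
  the marginal plateau, and rotation/flip augmentation — a regularizer
  for long training — only slows convergence, hence the scaled optimizer
  settings; the learnable-parameter structure is untouched.
* Grad-CAM localization: on the trained model, the mean heat inside the
  generator's lesion boxes must exceed the outside mean for the matching
  class on ≥ 70% of 100 diseased phantoms. At a 64 px input the last
  block's map is 2×2, so the check targets the block whose pre-pool map
  is 8×8 — the resolution the default target has at the full 224 input.
* Generator suite: 10,000 samples at 128 px for label/lesion consistency
  and 3-binomial-SE prevalence bounds; byte-identical regeneration
  checked at the native 512 side.

## Known limitations

* Stride > 1 convolutions are spec'd in `LayerSpec` for completeness but
  the runtime implements stride 1 (the SRN family needs nothing else);
  strides enter parameter/MAC accounting only.
* MAC counts follow the k²·Cin·Cout·positions convention and are not
  comparable to "FLOPs" figures produced by other toolchains, whose
  conventions (2×MACs, pooling/activation inclusion) vary.
* The 12-layer "non-factorized" comparison network is not constructible
  from public information and is not provided.
* Normalization layers are accepted as a config flag but intentionally
  unimplemented; the counted/published variants all exclude them.
* CPU NumPy training is practical at the suite's desk scale only.
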