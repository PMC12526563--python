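# Methods

`falsseg` implements a family of single-stage, anchor-free models for joint
detection and instance segmentation of tumor-like lesions in grayscale
medical images, together with everything needed to exercise them end to end
on one CPU: a small reverse-mode autograd engine on numpy, a synthetic
phantom generator with exact polygon labels, a trainer, and detection/
segmentation metrics.

## Model family

All four variants share one graph: a CSP-style backbone (stem conv, four
stage transitions, C2f blocks with depths 1/2/2/1, SPPF), a PAN neck fusing
strides 8/16/32, and a segmentation head emitting, per scale, box-side
distance distributions (`4 * reg_max` logits), class logits, and mask
coefficients, plus image-level prototype masks from the stride-8 feature map.
Widths follow the n-scale convention (16/32/64/128/256 channels).

* **baseline** — stride-2 3x3 convolutions for downsampling and the standard
  decoupled head with per-scale conv towers.
* **flrdown** — the four post-stem downsampling convolutions are replaced by
  FLRDown blocks.
* **flrdown_lscshn** — additionally swaps the head for the lightweight
  shared-convolution head (LSCSHN).
* **fals_yolo** — additionally gates each neck output with AdaSimAM
  attention (adds no parameters and, under the conv-only FLOP convention, no
  counted computation).

### FLRDown

The input (C1 channels) is split in half along channels.  The *spatial*
half passes through a low-rank factorised convolution: a plain 1x3 conv
(stride 1, no norm/bias, intermediate width C2/2) followed by a 3x1
conv+BatchNorm+SiLU with stride 2 in both dimensions — the only reading of
"the 3x1 convolution set to a stride of 2" that actually halves both axes.
The *frequency* half is low-pass filtered in the DFT domain: 2-D FFT per
channel, crop of the unshifted top-left quadrant (ceil(H/2) x ceil(W/2),
exclusive bounds), inverse DFT on the cropped grid, real part.  Because the
crop keeps only one member of each conjugate pair, all non-DC components
come back at half amplitude; the DC term is preserved exactly by scaling the
inverse with 1/(H·W) — the convention is pinned by requiring that a constant
map stays the same constant.  The result is aligned to the spatial branch's
output grid by bilinear interpolation (the identity for even inputs) and
refined by a plain 1x1 conv (C1/2 -> C2/2).  Concatenating the branches
yields the half-resolution, C2-channel output.  At every backbone site the
block is strictly cheaper than the 3x3 stride-2 conv it replaces.

Norm placement and the intermediate width of the factorised pair are not
derivable from the block's published description; they were fixed by
requiring the deploy-time parameter count of the whole flrdown variant to
equal the published 2,975,529 exactly (see "Parameter accounting" below).
The backward pass of the spectral op is its adjoint (zero-pad + forward DFT),
verified against finite differences and an inner-product identity.

### AdaSimAM

SimAM-style energy attention with three changes for noisy grayscale data:
statistics are computed on a smoothed copy of the map (stride-1 average
pooling, default 3x3); the global channel mean is replaced by a local
windowed mean (default 7x7, falling back to the global mean when the window
covers the map); and the regulariser lambda adapts per channel,
`lambda_c = max(sigma_c * alpha, lambda_floor)` with `alpha = 0.01` and
`lambda_floor = 1e-4` guarding zero-variance channels.  The gate is

    w = sigmoid( (x' - mu_local)^2 / (4 (sigma_hat^2 + lambda)) + 0.5 )

with `sigma_hat^2` the channel variance of the smoothed map (n = HW - 1
divisor) and the *original* map multiplied by `w`.  With a 1x1 smoothing
kernel, a window covering the map, and lambda pinned at the floor this
reduces exactly to plain SimAM, which is the oracle used in tests.  The
block has zero trainable parameters, so inserting it after the three neck
outputs leaves the parameter count untouched.

Average pooling normalises border windows by the number of in-image pixels
(not k^2), so constant maps are preserved exactly; the loop-based test
oracle uses the same convention.

### LSCSHN

Per-scale 1x1 Conv_GN compressors project the neck outputs (64/128/256
channels) to one hidden width (64); a single shared stack of two 3x3 Conv_GN
layers is applied at all scales (one weight set, gradients accumulate from
every scale).  One shared 1x1 conv emits the 4·reg_max box logits — a
per-scale learnable scalar (`Scale`, initialised 1.0) adjusts its output per
pyramid level, which is what makes a fully shared regression head viable —
and one shared 1x1 conv emits class logits.  Mask coefficients come from
per-scale towers on the raw neck features (1x1 Conv_GN to 32 channels, 3x3
Conv_GN, 1x1 conv to 32 coefficients).  Prototypes use the standard stack on
P3 (3x3 conv, 2x transposed conv, 3x3 conv, 1x1 conv; 64 channels, 32
prototypes at stride 4).  GroupNorm uses 16 groups and eps 1e-5; it
normalises per sample, so head behaviour is independent of batch
composition.  Box distances are decoded as the expectation of the softmax
over `reg_max = 16` bins.

The precise branch layout is again fixed by the published counts: with every
width at its canonical value this is the unique layout (in a broad template
family we searched) whose deploy-time count lands on 2,217,318 exactly while
the conv-FLOP total rounds to 9.6 GFLOPs.

## Parameter accounting and GFLOPs

`count_parameters` reports the deploy-time count: conv+BatchNorm pairs are
folded (weights + one bias per conv), GroupNorm keeps its 2C affine terms
(it cannot be folded), plain conv biases and the fixed 16-entry DFL
projection are included.  This is the convention under which the published
figures (3,258,649 / 2,975,529 / 2,217,318) are reproduced exactly; the raw
trainable count is available as `count_parameters_raw`.

`estimate_gflops` sums `2 · Hout · Wout · (Cin/groups) · Cout · Kh · Kw`
over all convolutions at the stated input size, counting the transposed
convolution over its output elements with its full kernel (the convention of
mainstream profilers) and the DFL decode as a 16->1 conv per box side.
Pooling, normalisation, activations, resampling and the FFT are excluded.
At 640x640 this yields 11.97 / 11.53 / 9.60 GFLOPs for baseline / flrdown /
fals_yolo, printing as 12.0 / 11.5 / 9.6 at one decimal.

## Losses and target assignment

Foreground anchors are chosen by a task-aligned assigner (top-k 10,
alpha 0.5, beta 6.0; anchors restricted to ground-truth interiors; conflicts
resolved by IoU; target scores normalised per object).  The default trainer
loss is the conventional one: CIoU + distribution focal loss on the box
branch, BCE against the aligned soft scores on the classification branch,
and box-cropped, area-normalised BCE between the assembled prototype
combination and the rasterised polygon on the mask branch (weights
7.5/0.5/1.5/1.0 for box/cls/dfl/seg).  `loss_mode="paper_eqs"` switches to
the printed formulation — summed squared coordinate error (image-normalised),
plain cross-entropy, the same DFL term, BCE+Dice (epsilon 1.0) on masks —
which is also exposed as standalone functions for unit testing.

Classification biases are initialised to the usual prior (about five objects
per image) and the shared regression final to 1.0, which keeps the first
epochs stable.

## Synthetic phantoms

Each phantom is a 640x640 (configurable) grayscale image: a smooth
elliptical "brain" blob with a few low-frequency cosine modes, plus Gaussian
noise (sigma 0.03 of the intensity range — visible speckle without burying
small lesions).  Zero to three elliptical lesions are placed inside the
blob: semi-axes 12–120 px at the 640 px reference scale (scaled
proportionally at other image sizes, with a 6 px semi-axis floor so every
lesion stays resolvable above the coarsest feature stride), random
orientation, intensity contrast drawn from [0.15, 0.6].  The three classes
differ in appearance: class 0 is uniformly bright, class 1 bright with a
sinusoidal internal texture whose period scales with the lesion (so the
class signature exists at every lesion size), class 2 dark.  Every lesion carries a 24-vertex polygon of its boundary whose
rasterisation matches the stored mask at IoU >= 0.98.  Generation is
deterministic in (seed, index), and train/val splits use disjoint index
ranges.

What the phantoms do **not** emulate: MRI physics (bias fields, partial
volume, modality contrast), anatomy, non-elliptical lesion shapes, or
inter-annotator label noise.  Passing the smoke test therefore demonstrates
that the architecture, losses, assigner and decoder are wired correctly and
can learn a lesion-segmentation task from scratch — not that the printed
clinical accuracy transfers.

## Training at desk scale

The trainer defaults mirror the published full-scale configuration
(SGD, lr 0.001, momentum 0.973, weight decay 5e-4, batch 32, 120 epochs,
640 px).  Those settings presume GPU-scale data and iterations; the
desk-scale smoke run in the acceptance suite instead uses the package's
small-data recipe: Adam (lr 0.004, one warmup epoch, linear decay to 10 %),
batch 2 at 160 px, loss weights 10/1.5/2/2 for box/cls/dfl/seg, random
horizontal/vertical flips, global gradient-norm clipping at 10, and no EMA.
Two stabilisers matter at this scale: the last BatchNorm gamma of every
residual bottleneck is initialised to zero (each block starts as identity),
and after the final epoch the BatchNorm running statistics are recalibrated
with one pass over the training images at the final weights.  Mosaic/MixUp
remain off by default (a `mosaic` flag exists).  Determinism: weight init,
shuffling, augmentation and the data itself all derive from the config
seed; reruns are bit-identical.  At this fixed desk scale (64 images,
10 epochs) held-out mAP@0.5 lands at roughly 0.50 ± 0.05 depending on the
training seed — a learnability check, not a converged result (longer runs
climb well past 0.8).

## Evaluation

Greedy confidence-descending matching at IoU 0.5 (box IoU or binary-mask IoU
per task), each ground truth consumed once; AP is the all-point interpolated
integral of the monotone precision envelope over recall (checked against a
dense-grid Riemann oracle); mAP@0.5 averages classes with defined AP,
warning on classes with no ground truth.  Inference applies a 0.001
confidence floor and class-aware NMS at IoU 0.7 before evaluation; the
confusion matrix uses a 0.25 confidence threshold and class-agnostic
matching so cross-class confusions are visible, with unmatched ground truths
and predictions booked against a background row/column.

## Numerical choices and limitations

* float32 throughout; sigmoid/SiLU inputs clipped at ±60 before
  exponentiation.
* BatchNorm: eps 1e-3, momentum 0.03.  Very early in training the running
  statistics lag the batch statistics, so eval-mode losses are initially
  inflated; they converge within a few dozen steps.
* DFL targets are clamped to [0, reg_max − 1 − 1e-3] with a warning in the
  standalone function.
* The engine implements only the ops these models need; convolution is
  im2col + BLAS matmul, which favours speed over memory on large inputs.
* Single-process, CPU-only: profiling a 640 px variant takes seconds, the
  acceptance smoke run a few minutes; full-scale (640 px, 120-epoch)
  training is out of reach and out of scope.
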