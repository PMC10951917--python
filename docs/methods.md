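# Methods

## Problem and model

`virtualstain` translates a multi-slice bright-field z-stack
x ∈ [0,1]^{S×H×W} into the fluorescent nuclei image that a DNA stain
(e.g. Hoechst) would show, and simultaneously assigns every pixel a
health state: *healthy*, *apoptotic* or *background*. Apoptotic nuclei
fragment (karyorrhexis), so they appear as clusters of small bright
spots with high internal intensity variance, while healthy nuclei are
smooth; bright-field alone shows cell bodies but barely shows nuclei,
which is why the translation is learned from paired data.

The model is a conditional GAN with a dual-output generator:

* a shared residual encoder (5 down-sampling sub-modules, each a 3×3
  shape-invariant convolution, a 4×4 stride-2 sampling convolution and a
  1×1 strided shortcut) plus a bottleneck;
* an **image decoder** (5 up-sampling sub-modules with encoder skips)
  ending in a 1×1 convolution and Tanh → 2 channels (healthy,
  apoptotic) in [−1, 1];
* a **mask decoder** of identical layout ending in SoftMax → 3
  per-pixel class probabilities (one more channel than the image head;
  the extra channel is background);
* the final translation gates the image by the mask:
  `translation[c] = image[c] · mask[c]` for the two nucleus channels.
  Targets keep the dark background at 0 (inside the Tanh range), which
  makes the gate consistent: where the mask says background, the product
  and the target both vanish.

**Cross-attention.** Between the five up-sampling layers lie four
intervals. A 4-digit binary placement code (digit 1 = deepest interval)
selects which intervals carry cross-attention modules. Each module runs
SAGAN-style self-attention on both decoder paths (1×1 query/key/value
projections with C/8 query/key channels, row-SoftMax over the H·W
positions, an output 1×1 projection, and a residual x + γ·o with γ
initialized to 0) and additionally computes a cross term whose query
comes from the image path and key/value from the mask path. The cross
branch keeps its own γ-residual on the image features; it is
concatenated with the image self-attention branch and reduced by a 1×1
projection initialized to average the two halves. Every attention module
is therefore an exact identity at initialization, and placement codes do
not change downstream shapes. The mask path receives no cross
information (a plain U-Net suffices for semantic segmentation).

**Discriminator.** A conditional PatchGAN: the bright-field stack and
the (real or generated) 2-channel image are concatenated and passed
through 4 encoder-style down-sampling sub-modules and a final 1-channel
3×3 convolution, giving an N×N grid of logits whose receptive fields are
bounded sub-windows. Self-attention (γ=0 at init) follows levels 3–4.

**Spectral normalization** is applied to every convolution weight in
both networks: weights (reshaped to out_channels × rest) are divided by
their leading singular value, estimated by power iteration with
persistent vectors — one iteration per training forward, many more in
evaluation mode where tight σ₁ estimates matter. Persistent vectors are
saved in checkpoints so inference is bit-reproducible.

## Objective

For patch logits r (real) and f (fake):
`loss_D = mean softplus(−r) + mean softplus(f)` and the non-saturating
`loss_G_adv = mean softplus(−f)`. The generator total is

```
L_G = loss_G_adv + λ·[α·L1 + (1−α)·(1 − SSIM)] + w(e)·CE(mask, labels)
```

with λ = 100 (reconstruction two orders above the adversarial term),
α = 0.5, SSIM computed with an 11×11 Gaussian window (σ = 1.5,
k₁ = 0.01, k₂ = 0.03 on the output dynamic range), and the dynamic mask
weight `w(e) = max(2.5, 250·0.9^⌊e/1500⌋)` — high early so the
segmentation path converges first and feeds reliable spatial structure
to the cross-attention modules, then decaying. Evaluation uses MAE,
SSIM and PSNR = 10·log₁₀(L²/MSE); the loss and the metrics share one
SSIM implementation. When the image is smaller than the window (or the
window is disabled) SSIM falls back to global uniform statistics.

## Numerical engine

The networks run on an in-package reverse-mode autodiff engine over
NumPy arrays: im2col/col2im convolutions and transposed convolutions
with exact adjoints, elementwise ops, SoftMax, and Adam
(β = (0.5, 0.999)). Compute dtype is float32 (float64 available via a
context manager; the test suite's finite-difference gradient checks run
in float64 and agree to ~1e-8). Gradients flow through the spectral
normalization σ (u, v held constant), matching the cited scheme.

## Ground-truth preparation

From a raw fluorescent z-stack: per-slice min–max normalization to
[0, 255]; maximum-intensity projection; CLAHE with clip limit 2 on an
8×8 tile grid (the clip maps to scikit-image's normalized limit as
2/256); 4 passes of Gaussian smoothing (5×5, σ=1 — reconnects fragments
of one apoptotic nucleus); 12 passes of 3×3 median filtering; Otsu
threshold; Euclidean distance transform; local maxima (min separation
7 px, ≥0.3 of the max distance) as markers; marker-controlled watershed
(8-connectivity). Per-nucleus intensity standard deviations on the
maximum image are split by a 1-D Otsu threshold: the high-variance group
is apoptotic. A single nucleus (or indistinguishable stds) defaults to
healthy with a warning, and a manual-override table reproduces curator
corrections. The 2-channel target is the CLAHE'd center slice masked by
the two state unions; bright-field slices are min–max normalized.

## Synthetic scenes

The generator emulates the statistics the method relies on, not optics:
healthy nuclei are sharp-edged ellipses of uniform moderate brightness
(radius 12–18 px on the default 256-px canvas, matching the relative
scale of nuclei at high magnification against the pipeline's fixed
kernel sizes); apoptotic nuclei are 3–8 condensed fragments (radius
2.5–4 px, brighter than intact chromatin, ≥1 px dark gaps); touching
pairs occur with probability 0.25 to exercise the watershed. Bright-field
slices show low-contrast cell-body edge rings (amplitude 0.06) around
each nucleus; the nucleus signal itself is phase-like: amplitude
0.12·tanh(Δz/0.45 μm), zero at focus and sign-reversed across it, with
defocus blur σ = 0.5 + 1.2·|Δz| px and additive Gaussian noise
(σ = 0.02). The emulated fluorescent z-stack uses a thinner PSF growth
(0.5 px/μm — confocal optical sectioning). Thirteen slices at 0.3 μm
are the default acquisition geometry; every scene is a pure function of
its seed.

What this does *not* emulate: real refractive structure inside cells,
photobleaching, 3-D fluorescence, stage drift, or nuclei at different
focal depths. Passing tests therefore demonstrate that the architecture,
losses and pipeline behave as designed under the assumed statistics —
not performance on real microscope data.

## Training protocol

Batch 8, Adam (0.5, 0.999), one discriminator step per generator step,
augmentation by random flips, 90°-multiple rotations (mask-safe) and a
random crop; train/validation folds reshuffled every 50 epochs with the
test split fixed; the best-validation-MAE checkpoint is retained.
Full-scale training runs thousands of epochs; the package's desk-scale
protocol — used by the test suite and reproducible end-to-end on one CPU
in minutes — is 16 scenes at 64×64, base_channels 8, batch 2, 30 epochs,
and learning rate 2×10⁻³ for both networks. The larger step size is
deliberate: with Adam the per-step parameter movement is bounded by the
learning rate, and a few hundred steps must visibly move the Tanh and
SoftMax heads; at full scale the conventional 10⁻⁴-range rates with TTUR
apply. Under this protocol the dual-path model ("0011") halves its
validation MAE and detects/classifies >50% of held-out nuclei, and the
two-channel no-mask ablation exhibits its characteristic collapse toward
one output channel (reported as a per-channel energy ratio).

## Detection scoring

Predicted nuclei are 8-connected components of the argmax foreground,
matched greedily one-to-one to truth instances by descending
intersection-over-truth (threshold 0.3 — tolerant of undersized
predictions). Unmatched predictions are false positives (normalized by
the number of detections); unmatched truths are false negatives and
misclassifications are normalized by the number of truth nuclei. The
report keeps raw counts so any alternative normalization can be
recomputed.

## Design choices and limitations

* Projection widths, channel schedules, crop sizes and learning rates
  are configurable because the architecture's published description
  leaves them open; defaults follow SAGAN/pix2pix conventions
  (channels/8 reductions, base 32 doubling to 512, LeakyReLU(0.2)
  encoder / ReLU decoders, 4×4 stride-2 sampling).
* The up-sampling shortcut is nearest-neighbour upsample + 1×1
  convolution (avoids checkerboard zeros of a strided 1×1 transpose).
* The background mask channel gates nothing; it participates only in
  the cross-entropy.
* Slice-count experiments use centered sub-stacks; off-grid separations
  round to the nearest slice with a warning.
* The engine is CPU-only and desk-scale by design; full-resolution
  training at publication scale would need a GPU framework.
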