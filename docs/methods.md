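# Methods

## Model

HEA-Net is a four-stage U-shaped segmentation network for binary masks.
Each encoder stage is a double 3×3 convolution (BN + ReLU) at widths
`base_width · (1, 2, 4, 8)`, followed by an Efficient Attention Module
(EAM) and a 2×2 max-pool; the bottleneck is a double convolution at the
deepest width followed by the Dual-channel Shift MLP (DS-MLP); the four
skip paths pass through a channel-wise cross fusion transformer (CCT); the
decoder upsamples bilinearly, gates each skip with channel cross attention
(CCA) computed from pooled decoder features, concatenates and convolves
back down; a 1×1 convolution emits one logit per pixel.  Inputs in [0, 1]
are standardised to `(x − 0.5)·4` at the network entry.

### EAM

Channel weights are the normalised absolute batch-norm scale factors
`ω_γ,i = |γ_i| / Σ|γ_j|`.  The absolute value is deliberate: γ may turn
negative during training, and |·| keeps the weights a convex combination
(they sum to one exactly).  The channel map is `ω_C = σ(ω_γ ⊗ BN(x))`;
BN carries the full affine transform and follows the usual contract
(batch statistics in training, running statistics at inference).

Spatial weights use the closed-form minimum of a per-neuron energy: with
channel mean μ̂ and *biased* (divide-by-M) variance σ̂² over the channel's
M = H·W pixels, `e_t* = 4(σ̂²+λ)/((t−μ̂)² + 2σ̂² + 2λ)` and the weight is
its reciprocal.  λ (default 1e-4) keeps the expression well-posed for
constant channels, where e* = 2 and the weight is exactly 0.5 — a closed
form the tests pin down.  Statistics are computed per channel *and per
batch element*.

The gate is `σ(ω_C ⊗ ω_S) ⊗ x`.  Since ω_C is already sigmoid-squashed,
this is a double squashing; it is implemented as written.  The "without
BN" ablation replaces ω_C by the uniform map 1/C and keeps everything
else.

### DS-MLP

The bottleneck block needs C divisible by 8.  The first channel half gets
the four-direction spatial shift with slice-assignment semantics (rows or
columns the shift does not write keep their values); the second half is
multiplied by `σ(conv1d_k3(GMP))` — a kernel-3, stride-1, zero-padded,
single-filter 1-D convolution over the channel axis of the global-max-
pooled descriptor, so there is no dimensionality reduction anywhere in the
gate.  The halves are fused by two-way split attention: the pooled sum of
both branches passes through a bottleneck MLP (hidden width max(C′/4, 4),
GELU) to per-channel logits for the two splits, softmaxed so the fusion is
a convex combination per channel.  A final linear projection C/2 → C
restores the stated shape contract; it is one layer — the printed output
MLP is not otherwise specified.

### CCT and CCA

Each skip is average-pool patch-embedded with patch sizes (8, 4, 2, 1)
from shallow to deep, the unique assignment making all four scales share
one token count d.  Per layer (L = 4) and head (N = 4): per-scale queries
and shared keys/values over the channel-concatenated token set; attention
logits `QᵀK/√d` are instance-normalised and softmaxed along the key-
channel axis; head outputs are averaged.  Layer normalisation is applied
before attention (per scale for queries, jointly for keys/values) and
before the MLP.  The blocks carry residual token streams around both the
attention and the MLP, following the channel-transformer skip design this
architecture adopts; with all projections zeroed a layer is exactly the
identity, which a test asserts.  The per-scale MLP uses expansion 2.
De-tokenisation is nearest up-broadcast.  CCA computes a per-channel
sigmoid gate from a linear map of the globally average-pooled decoder
feature, re-weights the skip and concatenates.

Head bookkeeping (full-width projections per head, averaged) and the MLP
expansion are this package's choices; the cited design is under-specified
at that level.

## Loss and metrics

The loss is `w_ce·BCE + w_dice·(1 − softDice)` with w_ce = w_dice = 0.5.
BCE is evaluated in the stable logit form softplus(z) − z·y; soft Dice
uses probabilities with smoothing ε = 1e-5 and is computed *per image*
then averaged, matching the evaluation metric, which is the mean of
per-image Dice/IoU.  Empty-prediction-vs-empty-mask scores Dice = IoU = 1.
IoU = Dice/(2 − Dice) holds identically and is tested in exact
arithmetic.

## Training recipe

Adam (lr 1e-3, β = 0.9/0.999), batch size 4, fixed epoch budget, constant
learning rate by default (a cosine option exists but measured slightly
worse at short budgets and is off), online augmentation on the training
split only (independent 0.5-probability horizontal/vertical flips and a
uniform rotation in ±30°, the same geometric transform for image and
mask, both with reflect fill so border labels stay consistent with the
reflected tissue; masks re-binarised at 0.5).  When a validation split is
configured the best checkpoint by validation Dice is kept; with
`val_fraction=0` the final model is used.  After training, batch-norm
running statistics are recomputed exactly over the training set
("precise BN"), replacing the lagging exponential estimates.  A
non-finite loss aborts with epoch/step diagnostics.

## Synthetic data

The generators emulate the two benchmark regimes rather than their
photorealistic appearance:

* **gland**: 2–6 polar-perturbed ellipses (radius 0.18–0.32 of the image)
  with bright interior lumens that remain part of the gland mask, a
  textured background whose mean grayscale sits only `intensity_gap`
  (default 0.12) away from the foreground, and Gaussian boundary blur
  (σ = 1.5) — the high-similarity, blurred-boundary case.
* **nuclei**: 30–120 small ellipses (radius 2–5 % of the image), a
  configured fraction (default 0.3) placed adjacent to an existing
  nucleus; the rest are rejection-sampled away from neighbours so the
  connected-component count tracks the touching fraction.  Per-image
  stain-like colour jitter.

Masks are rasterised from the exact geometry before any blurring, so
labels are exact by construction; identical parameters and seed reproduce
datasets bitwise.  What the generators do *not* model: real stain
variability, imaging artefacts, annotation noise, instance labels, and
the long-tailed morphology of real tissue — so passing the desk-scale
experiments demonstrates that the implementation learns and generalises
within this controlled regime, not benchmark-level performance.

## Numerical core

The package carries a tape-based reverse-mode autodiff engine over numpy
(float32 by default; float64 selectable for reference comparisons, which
the oracle tests use).  Convolution is im2col + GEMM with the column
matrix recomputed during the backward pass to keep tape memory small;
max-pool gradients split ties evenly; bilinear ×2 upsampling is a pair of
cached 1-D interpolation matrices (align-corners-false convention).  All
primitive gradients are validated against central finite differences.

## Desk-scale experiment sizes

Chosen so the whole suite runs on one CPU: the overfit probe uses base
width 16 at 64×64 on one batch of four (≤200 Adam steps, early exit once
train Dice ≥ 0.95); the end-to-end experiment trains the same
architecture for 10 epochs on 64 gland images and evaluates 16 held-out
ones; the ablation study trains the +EAM, +DS-MLP and full variants at
base width 8 on 48×48 images for 6 epochs over five seeds (three in the
acceptance script).  At these sizes the between-variant Dice differences
(≈0.005–0.02) are of the same order as seed-to-seed noise, so the
ablation ordering is reported but should be read as under-powered; the
single-module ablations were designed to show sub-point margins only at
full benchmark scale.

## Known limitations

* Binary segmentation only; no multi-class head, deep supervision or
  pretrained weights.
* The numpy engine is single-threaded BLAS-bound; full-width 224×224
  training is out of reach — the package targets reduced widths and
  resolutions.
* The untrained network saturates to a near-uniform prediction (batch-norm
  running statistics are meaningless before training), so its Dice equals
  roughly 2f/(1+f) for foreground fraction f when it saturates positive.
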