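# Methods

This package implements a conditional contrastive GAN (CCGAN) for semantic
segmentation of images with severe class imbalance — the regime of lesion
segmentation in MRI and ultrasound, where healthy background dominates and
the foreground of interest covers a few percent of the pixels.  The method
combines four ingredients: a conditional adversarial segmenter, a
class-specific channel attention mechanism, region-level rebalancing of the
training signal, and a supervised contrastive correction network (SCoLN) that
edits the segmenter's false negatives and false positives.

## Model

**Conditional GAN.**  The generator G is a UNet-style encoder–decoder mapping
an input image `a` (plus latent noise `n`, realised as train-time dropout in
the bottleneck, the pix2pix convention) to per-pixel class probabilities
`G(a, n)`.  The discriminator D sees `(image, mask)` pairs — either the
ground truth `(a, o_seg)` or the generated `(a, G(a, n))` — and plays the
usual minimax game

    min_G max_D  E[log D(a, o_seg)] + E[log(1 − D(a, G(a, n)))].

The generator's adversarial term is implemented in the non-saturating form
(−log D on generated pairs).  Binary problems use a 2-channel softmax head so
the L-class path is uniform.

**2C conditional contrastive loss.**  The discriminator also emits a
projection `l(I)` per image, and owns a learned embedding `e(y)` per class.
For an anchor image `i` with class `y_i` and temperature `t`,

    2C_i = −log [ exp(⟨l_i, e_{y_i}⟩/t) + Σ_{j≠i, y_j=y_i} exp(⟨l_i, l_j⟩/t) ]
               / [ exp(⟨l_i, e_{y_i}⟩/t) + Σ_{j≠i}          exp(⟨l_i, l_j⟩/t) ],

averaged over anchors.  The numerator's index set is a subset of the
denominator's, so the loss is non-negative and zero exactly when all
cross-class similarity terms vanish.  The 2C loss is computed on real images
during the discriminator phase and on generated probability maps during the
generator phase.  For segmentation the image-level "class" is not canonical;
this package uses *foreground present* (binary) as the image label
(`TrainConfig.class_id_rule`).

**Class-specific attention.**  At configurable generator levels (defaults 2
and 6, i.e. the second encoder and second decoder block), the incoming
feature map is transformed by a depth-wise separable 3×3 convolution +
batch norm + ReLU into `x·L` channels grouped contiguously by class (`x`
channels per class, default 4).  Per class, global max pooling followed by a
mean over the class's channels gives a score `C_j`; a plain mean over the
class's channels gives a semantic plane.  The attention map is the
score-weighted mean of the semantic planes, applied multiplicatively to the
block input, so the block preserves shape and composes anywhere.  Two
ambiguities in the published formulation are resolved as follows and
surfaced here rather than silently fixed: the semantic-map normaliser `K` is
read as `x`, and the score–map product is read as a score-weighted sum of
class planes (a literal matrix product is dimensionally impossible).  No
squashing is applied to the attention map by default; a sigmoid gate is
available (`sigmoid_attention`) for stability on deeper configurations.

**Region-level rebalancing (RRM).**  Pixels are spatially correlated, so
pixel-frequency reweighting is unreliable; instead label maps are tiled into
non-overlapping `r×r` regions (default 32).  Dataset-level frequencies
`F(C)` count, over the *training fold only*, the regions containing class
`C` (a tile containing two classes increments both counts; a majority rule
is available).  The auxiliary region classifier (3×3 conv + ReLU + global
average pooling + dense) predicts each region's label from the deepest
encoder features, with the frequency-weighted cross-entropy

    L_reg = −mean_i log( F(y_i) e^{z_iy} / Σ_k F(k) e^{z_ik} ),

i.e. a logit adjustment by `+log F`: boosting the majority class *during
training* makes the learned logits themselves prior-corrected.  Frequencies
get add-one smoothing because the loss is undefined for `F(y)=0`.  The total
segmentation objective during the generator phase adds the pixel
cross-entropy plus `L_reg` when RRM is enabled.  The head is detachable:
inference never executes it, and the tests verify bit-identical
segmentations with the head attached or removed.

**SCoLN.**  A UNet corrector (bilinear upsampling decoder) receives the
image and the generator's probability map and predicts two maps in [0, 1]:
the false-negative map `C_ln = clamp(g − p, 0, 1)` and false-positive map
`C_lp = clamp(p − g, 0, 1)`.  It is trained with pixelwise binary
cross-entropy against the oracle maps of the current generator output, plus
a supervised contrastive term over bottleneck embeddings.  The published
pair-construction rule is not stated; here batch samples are grouped by
whether their pixel error exceeds the batch median, same-group samples are
positives, the rest negatives.  The published contrastive expression has no
minus sign and would reward similarity to negatives; the default corrected
form is `−log(Σ_pos / (Σ_pos + Σ_neg))` over exponentiated cosine
similarities, and the literal form ships behind `as_printed=True` without
any claim that it trains well.  The final mask is

    binarize( clamp(p + C_ln − C_lp, 0, 1) ≥ threshold ),

which with oracle maps reproduces the ground truth exactly for any
prediction in [0, 1] (verified exhaustively on 3×3 grids).  In the final
objective the FN/FP "counts" enter as spatial means so the loss magnitude is
resolution-independent (raw sums available via `raw_counts=True`).

**Three-phase training.**  Each batch runs discriminator → generator → SCoLN,
each phase updating only its own parameters (asserted bitwise in the tests).
The published order lists generator training first; classic GAN practice
suggests no material order dependence and the order is configurable in
`train_step(phases=...)`.  SCoLN trains concurrently with the GAN (the
alternative, post-hoc training, was the open choice; concurrent keeps the
corrector matched to the generator's current error profile).  One generator
forward pass per step serves all three phases (live graph for the G phase,
detached probabilities for D and SCoLN).

## Numerical backend

No deep-learning framework is assumed: the networks run on an in-package
reverse-mode autodiff core over float32 numpy arrays (NHWC).  Convolutions
are im2col + single GEMM; every primitive (including the fused batch norm
and factor-2 bilinear upsampling) is validated against central-difference
gradients in float64.  All contrastive and rebalanced losses are evaluated
in log-sum-exp-stabilised form and pinned to naive scalar-loop oracles
within 1e−6.

## Parameters

| Parameter | Default | Notes |
|---|---|---|
| temperature `t` | 3 | contrastive softmax sharpness (published value) |
| batch size | 32 | published; desk-scale runs use 8 for more updates/epoch |
| optimizer | Adadelta, lr 0.001, wd 1e−4 | published schedule; Adam offered because Adadelta at lr 0.001 is nonstandard and stalls at desk scale |
| epochs | 30 desk (450 published) | early stopping on validation Dice, patience 20 |
| region size `r` | 32 px | the region classifier's published input size |
| channels per class `x` | 4 | unpublished; small to keep the attention head cheap |
| levels / base filters | 4 / 16 | desk-scale depth and width; published kernel sizes (5×5 first block, 3×3 elsewhere) are kept |
| projection dim `d` | 64 | discriminator/SCoLN embedding width |
| λ_L1, λ_adv, region weight | 1 | unit weights as published; configurable |
| resize | 512×512 (real data), 64×64 synthetic | published resize vs. desk default |
| CLAHE | clip 2.0, 8×8 tiles | technique named without parameters; common defaults, delegated to scikit-image |

Preprocessing is per-sample: resize (bilinear image / nearest mask),
optional CLAHE, then per-channel Z-score.  Constant channels divide by 1,
so blank slices normalise to zero rather than NaN.  Whether single-channel
MRI should be replicated to three channels is unstated in the source
description; a `replicate_channels` flag is exposed rather than guessing.
Masks are only ever resized nearest-neighbour to preserve label integrality.

## Synthetic benchmark

`generate_synthetic` emulates the imbalanced-lesion regime: a smoothed
Gaussian speckle background (blur σ = 1, unit contrast) with 1–3 elliptical
lesions at intensity offset +2, dataset-mean foreground fraction 3%,
200 images of 64×64 by default.  Lesion areas are drawn per image from a
jittered budget split by a Dirichlet, with random eccentricity (1–2.5) and
orientation.  It does *not* emulate: anatomy-correlated background texture,
partial-volume soft edges, scanner bias fields, inter-slice correlation, or
ambiguous lesion boundaries.  A green end-to-end test therefore establishes
that the full pipeline learns and that its modules help in the intended
direction — not clinical-grade performance.

## Evaluation

Dice, Jaccard, precision, recall from pixel confusion counts with foreground
positive; computed per sample, reported as mean ± sample sd per fold and
pooled.  The published metric table swaps the IoU and DSC formulas relative
to their universal definitions; this package exposes the standard names
(dice = 2TP/(2TP+FP+FN), jaccard = TP/(TP+FP+FN)) and makes no claim about
which convention produced the published tables.  Conventions: both masks
empty → all metrics 1; empty prediction against non-empty truth → recall 0,
precision 1, with a `degenerate` flag in the record.

## Desk-scale acceptance configuration

The end-to-end acceptance run trains on the default benchmark (200 images,
64×64, 3% foreground, seed 0) with the Adam option, batch 8, ≤ 24 epochs,
patience 6, one train/validation split — chosen to fit a single-CPU budget.
The five-seed ablation comparison (full model vs. attention+RRM+SCoLN all
disabled) runs at reduced scale (60 images, 32×32, 6 epochs, a
3-level/8-filter network) to keep the suite inside its CI budget; it asserts
only the direction of the median Dice difference, not magnitudes.

## Known limitations

- CPU-only and desk-scale; no GPU path, no mixed precision.
- 2-D only; NIfTI volumes are segmented slice-wise.
- The multi-resolution image-pyramid reading of the published skip
  description is not implemented; skips are standard UNet concatenations.
- The GAN equilibrium is not tuned for large images; attention without the
  sigmoid gate can be aggressive on deep, wide configurations.
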