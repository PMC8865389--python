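# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would want spelled out.

## Problem setting

A digitized skin-biopsy slide usually carries several physically separate
tissue sections ("slices") on a bright background. The slide has one
diagnostic category from a severity-ordered four-class scale — MMD, MIS,
pT1a, pT1b — but only the slice(s) containing the consensus region of
interest (ROI) actually support that diagnosis; the other slices frequently
show less advanced tissue. Supervising every slice with the slide label (the
multiple-instance-learning default) therefore injects systematically wrong
targets. The pipeline addresses this with per-slice soft labels under an
ordinal constraint, and classifies slices with a transformer that fuses
information across patches and across magnifications.

## Slide preparation

Tissue is darker than background, so Otsu's threshold on the luma channel
separates them. The mask is cleaned in two stages:

1. *noise removal*: opening then closing with a disk of radius
   `max(3, 0.2 % of the smaller image dimension)`, then hole filling;
2. *consolidation*: a second closing with a disk of radius
   `max(10, 1 % of the smaller image dimension)`, then hole filling again.

The second stage reconnects fragments of one section that pale tissue
regions (lumens, fat, washed-out areas) can sever at the threshold step. Its
radius must stay below half the smallest expected gap between distinct
sections; with the generator's ≥ 40 px gaps the default can only bridge
within-section breaks. Connected components below 0.1 % of the image area
are dropped; survivors become `TissueSlice` objects sorted by descending
area. An image with no surviving component yields an empty list and a
logged warning, not an exception.

Crops at the non-base scales are taken by rescaling the base-scale bounding
box by the relative magnification factor. Patch tiling pads the crop
bottom/right with its median border color to dimensions divisible by `√m`,
then cuts a row-major `√m × √m` grid; `m` must be a perfect square. Patch
counts default to 25/49/81 at 0.75×/1×/1.25× so patch footprints cover
comparable tissue area across scales. Coordinates are 0-based with
half-open boxes.

## Soft labels from singular-value signatures

Every slice crop is converted to grayscale in [0, 1] and resized to a
canonical 512 × 512 before the SVD — singular values scale with matrix
size, so a canonical size is what makes profiles of differently sized
slices comparable. The signature is the descending vector of the top
`d = 50` singular values, zero-padded when the rank is lower.

Per-category prototypes are arithmetic means of the signatures of
ROI-bearing slices (every category must contribute at least one; a missing
category is a hard error naming it). A non-ROI slice's soft label is the
softmax of its signature's similarity to each prototype. Two numerical
choices here:

* **Cosine logits.** Raw singular values of a 512 × 512 [0, 1] matrix have
  norms of order 10³, so raw dot products (order 10⁴–10⁵) would saturate the
  softmax into a one-hot vector. Signature and prototypes are therefore
  l2-normalized before the dot product. Softmax is monotone, so the argmax
  is unchanged; the resulting vectors are genuinely soft.
* **Constraint denominator.** The diagnostic constraint zeroes categories
  `≥ k` (the slide's category) and renormalizes over categories `< k`.
  Renormalizing over `c < k` (not `c ≤ k`) is the reading that reproduces
  the worked four-class examples ([0.46, 0.39, 0.08, 0.07] → [0.54, 0.46,
  0, 0] at k = 3).

Slides of category 1 have no lower category; all their slices receive the
hard class-1 label. ROI-bearing slices always keep the hard slide label.
Baselines: hard one-hot; smoothing with `1 − ε` on the true category and
`ε/(C−1)` elsewhere (ε = 0.1); constrained smoothing with a uniform
distribution over categories `< k` for non-ROI slices.

## Model

Patch features come from a *frozen* extractor, so they are computed once
and cached; the optimizer never sees them. The default extractor is a
seeded random-weight CNN (three 3×3 stride-2 conv/ReLU stages, channels
24→48→192, global average pooling, inputs bilinearly resized to 48 × 48 and
centered). Random convolution banks respond differently to different
texture frequencies and contrasts — exactly the signal the synthetic
classes carry — in the spirit of random-feature methods. Any callable
mapping an RGB patch batch to fixed-width vectors (e.g. a pretrained
ImageNet CNN) can be substituted; only the configured native width changes.

The trainable head: a shared linear projection to `e = 128`; per-scale
2-unit transformers (4 heads, FFN width 512); mean pooling over patches;
a cross-scale 2-unit transformer over the stacked pooled vectors with
learnable scale-position embeddings; a linear classifier on the flattened
`S·e` vector. Units are pre-norm (`x + Attn(LN(x))`, `x + FFN(LN(x))`) with
a final layer norm — the sub-module order is fixed but norm placement was
an open choice; pre-norm trains more stably at small scale. Attention
logits are scaled by `1/√(e/heads)`; `attention_scaling=False` switches to
the literal unscaled dot-product form. Patch positions are 1-D sinusoidal
encodings of the row-major patch index (no 2-D structure is assumed).
Per-scale transformers have separate weights by default
(`share_patch_transformer=True` shares one stack); the projection is shared
across scales.

Everything runs on a small reverse-mode autodiff core over numpy float64
arrays; every primitive and the full forward pass are verified against
finite differences in the test suite.

## Training and inference

Adam (β = 0.9/0.999, ε = 1e-8, no weight decay) on one tissue slice per
step, all scales together. Learning rate: linear warmup 1e-6 → 5e-4 over
the first 500 steps, then constant with halvings at epochs 100 and 150
(training default 200 epochs; desk-scale runs use fewer). After each epoch
the slide-level validation accuracy (max-voting over slice argmaxes) is
recorded and the parameters snapshotted into a capacity-5 set ranked by
score, ties broken toward the earlier epoch. At the end the element-wise
averages of the best-3 and best-5 snapshots are compared on validation and
the better one is kept. Slide-level scores for ROC-AUC are the mean of the
slice probability vectors; the predicted slide label is the max-vote, i.e.
the most severe slice prediction — one invasive slice makes the slide
invasive.

## Evaluation

Overall: accuracy, micro-averaged F1 and sensitivity (identically equal to
accuracy for single-label multi-class predictions), micro one-vs-rest
specificity (equal to `((C−2) + accuracy)/(C−1)`, *not* to accuracy), and
macro one-vs-rest ROC-AUC with categories absent from the truth excluded
from the mean under a warning. Per category: one-vs-rest sensitivity,
specificity and F1, with per-category "accuracy" reported as recall (the
convention in per-category diagnostic tables); categories without true
slides are reported as undefined, not zero.

## Synthetic data

The generator emulates the features the pipeline depends on: bright
background (gray 0.93 plus mild sensor noise), 1–4 non-overlapping
elliptical tissue blobs per slide (semi-axes 80–160 px on a 1000 × 1200
base, inter-blob gaps ≥ 40 px), H&E-like tint, exactly one ROI blob
carrying the slide's category, and non-ROI blobs drawn uniformly from the
categories ≤ the slide's. Category texture is unit-variance Gaussian
band-limited noise with per-category smoothing length (1.2/2.8/5.5/10 px)
and contrast (0.10/0.13/0.16/0.19); the modulation is clipped at ±2σ so
tissue stays darker than background by construction. Smoother, higher-
contrast texture concentrates spectral energy in fewer singular values, so
the singular-value signatures — and the random-CNN features — separate the
categories by construction. Splits are stratified per category at
102/23/115-of-240 proportions. All randomness flows from one explicit
seeded generator; a fixed seed reproduces the dataset byte for byte.

What it does **not** emulate: stain variation, nuclei/cellular morphology,
scanner artifacts, annotation noise, or any real texture statistics of
melanocytic lesions. Passing the end-to-end checks shows the pipeline's
machinery works and that the ordinal soft-label mechanism helps when
non-ROI slices genuinely belong to lower categories; it says nothing about
accuracy on real biopsy images.

## Desk-scale run sizes

The shipped experiments use 40 slides (≈ 115 slices), three scales, the
default architecture, 30 epochs on cached features, and seed 7 for the
dataset — sizes chosen so a complete run finishes in minutes on one CPU
core while every qualitative claim (beats majority baseline; constrained
soft labels do not underperform hard labels) is exercised end to end.

## Known limitations

* The default backbone is untrained; with a pretrained CNN the absolute
  accuracies would differ (the interface accepts any extractor).
* Eight-bit PNG rendering quantizes the synthetic textures; profiles are
  computed from the quantized images, matching what a real pipeline sees.
* `m` must be a perfect square; rectangular grids are out of scope.
* Pyramidal/tiled slide formats are not read natively; slides enter as
  ordinary rasters per scale.
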