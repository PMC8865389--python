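# scaleformer

Scale-aware transformer pipeline for classifying multi-slice skin-biopsy
slide images into the four severity-ordered melanocytic diagnostic
categories — MMD (mild/moderate dysplastic nevi), MIS (melanoma in situ),
pT1a and pT1b (invasive melanoma stages) — with diagnostically constrained
soft labels for tissue slices that lack a region of interest (ROI).

It is aimed at computational-pathology researchers who want a fully
inspectable, CPU-sized implementation of the whole chain: tissue-slice
segmentation, multi-scale patch tiling, frozen-CNN patch embeddings,
per-scale and cross-scale transformer fusion, soft-label construction from
singular-value signatures, training with checkpoint averaging, and
slide-level max-voting evaluation. A seeded synthetic-slide generator makes
every stage testable without any external data.

## The model

A slide is rendered at `S ≤ 3` relative magnifications (0.75×, 1×, 1.25×,
tagged 7.5x/10x/12.5x). Each tissue slice is tiled into `m` non-overlapping
patches per scale (`m` = 25/49/81 at the three scales). For scale `sc`:

1. `PE_i = CNN(x_i)` — a frozen CNN embeds each patch independently; a
   shared linear projection maps the native width to `e = 128`.
2. `CPE = Transformer(PE + PPE)` — sinusoidal patch positions `PPE` are
   added and a 2-unit pre-norm transformer (4 heads, FFN width 512) mixes
   the patches; rows are mean-pooled to one vector per scale.
3. `CSE = Transformer(SE + PSE)` — pooled vectors are stacked into `SE`,
   learnable scale positions `PSE` are added, a second transformer mixes the
   scales, and the flattened `S·e` vector goes through a linear classifier
   to `C = 4` scores.

Slide-level predictions max-vote over slice predictions: the most severe
predicted category wins.

**Soft labels.** Slices with an ROI keep the hard slide label. A non-ROI
slice `j` is summarized by the descending vector `ŝ_j` of its top-`d = 50`
singular values (grayscale, canonical 512×512 resize); per-category
prototypes `s̄_i` are the means over ROI-bearing slices, and

```
ŷ_j = softmax(s̄ · ŝ_j),   ỹ_cj = ŷ_cj / Σ_{c<k} ŷ_cj  if c < k,  else 0
```

where `k` is the slide's category — a non-ROI slice can only belong to a
*lower* category than its slide. Profiles are l2-normalized before the dot
product (cosine-similarity logits). Hard, smoothed (`1−ε` / `ε/(C−1)`), and
constrained-smoothed baselines are provided for comparison.

Training uses Adam with linear warmup 1e-6 → 5e-4 over 500 steps, halvings
at epochs 100/150, a frozen backbone, and element-wise averaging of the
best-3/best-5 validation checkpoints.

## Worked example

Constrained soft labels for a pT1a slide (`python examples/01_constrained_soft_labels.py`):

```
soft [0.46, 0.39, 0.08, 0.07] -> constrained [0.54, 0.46, 0.0, 0.0]
soft [0.21, 0.54, 0.1, 0.15] -> constrained [0.28, 0.72, 0.0, 0.0]

Baseline schemes for the same slide (class 3, epsilon = 0.1):
  hard                : [0.0, 0.0, 1.0, 0.0]
  smoothed            : [0.033, 0.033, 0.9, 0.033]
  constrained smoothed: [0.5, 0.5, 0.0, 0.0]
```

Categories 3–4 are zeroed because a slice without the diagnostic region
cannot itself be invasive melanoma; the remaining mass is renormalized.

End-to-end on the seeded 40-slide synthetic dataset
(`python examples/03_train_on_synthetic_slides.py`, a few minutes on one CPU):

```
40 slides, 114 tissue slices
             hard: test accuracy 0.40 (majority baseline 0.25, macro AUC 0.72)
 constrained_soft: test accuracy 0.50 (majority baseline 0.25, macro AUC 0.91)
```

Hard labels copy the slide category onto every slice — wrong for most
non-ROI slices — while constrained soft labels supervise them with their
plausible lower categories, which lifts test accuracy and AUC.

There is also a thin CLI (`scaleformer synth / prepare / softlabel / train /
predict / evaluate`); run `scaleformer --help` for the verbs.

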