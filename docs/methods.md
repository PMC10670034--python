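# Methods

`xwclust` implements a four-step knowledge-discovery procedure for binary
image-classification problems in which the positive ("pathological") class is
suspected to contain several distinct characteristics that no label
distinguishes:

1. train a classifier f(I) → ŷ ∈ [0, 1] on healthy vs. pathological images;
2. compute an occlusion-based visual explanation for every image classified
   pathological;
3. weight each image by the non-negative part of its explanation,
   I_Y = I ⊙ Y⁺;
4. cluster the weighted images and read the subtypes off the clusters.

This note records the model choices, the defaults and why they hold, what the
synthetic data does and does not emulate, and the numerical conventions.

## Occlusion attribution

A gray patch (C = 128/255 in every channel, exactly) of size P_W×P_H slides
over the image with stride s; the attribution of pixel j is the mean drop in
probability over the patches covering it:

    Y_j = (1/|J|) Σ_{i∈J} ( f(I) − g(I, P_i) ),   g(I, P) = f(I ⊙ P + (1−P) ⊙ C).

Conventions:

- The regular stride grid is augmented with a final row/column of patches
  clamped flush to the bottom/right edges, so every pixel is covered for any
  (patch, stride) with stride ≤ patch; strides larger than the patch are
  rejected (interior pixels would never be occluded).
- f(I) is evaluated once per image; occluded variants are evaluated in
  batches. Evaluation is pure, so batching cannot change the result (tested).
- Explanations carry a known systematic offset toward the top-left of the
  attributed object, a joint artifact of the left-to-right/top-to-bottom patch
  sweep, the patch size and the architecture. It is documented behavior and
  deliberately not corrected.

Raw maps are normalized per image — positives divided by the maximum
positive, negatives by the absolute minimum — giving values in [−1, 1] with
both extremes attained. Per-image (rather than per-dataset) normalization
keeps each explanation self-contained; it is also what makes downstream
weighting comparable across images whose absolute probability drops differ by
orders of magnitude (a confidently classified image may move by 10⁻⁴ only).

## Smoothing function

Normalized values are sharpened by the two-branch power transform

    S(x, θ, σ) = x^σ / θ^(σ−1)              x ≤ θ
                 1 − (1−x)^σ / (1−θ)^(σ−1)  x > θ

with offset θ ∈ (0, 1) and strength σ ≥ 1. S fixes 0, θ and 1, is continuous
at θ and strictly increasing on [0, 1]; values below θ are suppressed toward
0, values above are amplified toward 1. Defaults θ = 0.1, σ = 8. Negative
entries are smoothed by magnitude with the sign restored, so the red/green
overlay semantics stay symmetric. There is no automatic procedure for
choosing θ and σ; they are visual-quality parameters.

## Classifier

The framework is model-agnostic: everything downstream sees only a
probability and a penultimate-layer feature vector. The bundled `small_cnn`
is a compact conv-net — 3×3 same-padding convolutions with channels
(8, 16, 32, 256), ReLU, 2×2 max-pooling after the first three blocks, global
average pooling (the 256-d penultimate feature vector), and a single sigmoid
logit. The final activation is a sigmoid: a one-neuron head admits no other
reading consistent with ŷ ∈ [0, 1] carrying information and with binary
cross-entropy. Inputs are centered to [−0.5, 0.5] inside the forward pass;
with raw [0, 1] inputs the first-layer gradients share a common bias
direction and training reliably stalls on the subtler (blob) subtype.

Training: SGD with momentum 0.9, binary cross-entropy, learning rate decayed
by 0.1 every 7 epochs, early stopping when validation F1 fails to improve for
5 consecutive epochs, weights restored to the *first* best-validation epoch.
The first-best rule matters: training past the epoch where validation
saturates keeps shrinking the loss by growing the logit, which collapses the
feature diversity the clustering stage depends on (measured: held-out Rand
drops from 1.0 to ≈0.55–0.8 when restoring the last tied-best epoch instead).
Defaults lr = 0.05 and batch 16 are sized for from-scratch training on a few
hundred images; the fine-tuning recipe (lr 0.001, batch 64) is expressible
through `TrainConfig` and appropriate when a pretrained backbone is used. A
`resnet50_transfer` architecture (ImageNet-pretrained 50-layer residual
network with a one-neuron head) is supported when the optional
torch/torchvision extra is installed; nothing in the tests requires it.

## Explanation weighting and embedding

Y⁺ = max(Y, 0) is broadcast over the channels and multiplied into the image.
Weighted images are embedded with the penultimate features of the same
trained classifier (an alternative handle — e.g. an untrained network — can
be passed for baseline comparisons). Three nuisance factors are removed at
the embedding step, each measured to otherwise dominate the Euclidean
geometry and fragment silhouette-driven model selection:

- **Position canonicalization** (default on): each weighted image is
  circularly shifted so its intensity centroid sits at the frame center.
  The surround of a cut-out is black, so nothing of consequence wraps.
  Without it, shapes near the frame edge embed measurably differently from
  centered ones (halo clipping plus convolution boundary effects) and the
  top SVD direction correlates strongly with edge distance.
- **Dihedral averaging** (default on): features are averaged over the 8
  flips/rotations of the weighted image; orientation is irrelevant to the
  subtype.
- **Row L2-normalization** (default on): the norm of a global-average-pooled
  embedding tracks the total surviving explanation mass; the direction
  carries the content. Without normalization the top SVD direction is
  explanation mass, and K-means partitions along it.

Features are then column-centered and reduced by SVD to the smallest
dimension capturing 90% of variance, capped at min(32, n−1). The projection
is stored so held-out images can be mapped into the same space.

## Clustering and scoring

K-means (k-means++ initialization, Lloyd iterations, best of 10 restarts by
inertia) is run for K = 2..6; the K with the highest silhouette coefficient
wins, ties toward smaller K. Distances are Euclidean throughout. Held-out
images are assigned to the nearest centroid (ties to the lowest index).
Scores:

- plain Rand index (pair-counting agreement, permutation-invariant; the
  adjusted form is available behind a flag);
- silhouette coefficient, mean of (b−a)/max(a, b) with singletons scoring 0;
- Davies–Bouldin index, mean over clusters of the worst
  (s_i + s_j)/d_ij ratio.

Silhouette and Davies–Bouldin compute distances through
`scipy.spatial.distance.cdist`; the quadratic-expansion Euclidean shortcut
loses ~10⁻⁸ of precision, noticeable when near-tied clusterings are compared.

Only images the classifier calls pathological (ŷ ≥ 0.5) are explained and
clustered. Clusters are fit on the train+validation pathological images; the
test split is the held-out set whose nearest-centroid assignment yields the
reported held-out Rand index (in-sample Rand is reported alongside).

## Synthetic data

The generator emulates lower-GI endoscopy frames at desk scale: smooth
low-frequency textures in a red/pink palette (coarse random grid upsampled
bicubically, plus fine grain), an optional green picture-in-picture inset in
the bottom-left corner (rate 0.3) acting as a confounder, and pathological
images built from the *same* background as their healthy counterpart with
exactly one colored overlay:

- `yellow_rect` — axis-aligned yellow (1, 1, 0) rectangle;
- `blue_ellipse` — blue (0.10, 0.25, 0.90) ellipse, rasterized by an
  inclusive point-in-ellipse test so the pixel count tracks πab;
- `pink_blob` — a polyp stand-in: pink (0.95, 0.55, 0.75) deformed ellipse
  whose radius is modulated by a low-order Fourier series clipped to
  [0.7, 1.0], so it is irregular but never exceeds its nominal bounding box.

Shape width and height are drawn uniformly from 20–25% of the image side;
placement is uniform over positions keeping the shape fully inside the frame
(overlap with the PiP inset is allowed — removing it would soften the
intended confounder). Class balance is exact; subtype draws are independent
Bernoulli by default with a `--stratified` option for exact counts. Splits
are 64/16/20% train/val/test, assigned per (label, subtype) stratum with
largest-remainder rounding. Images are 8-bit PNGs; masks are {0, 255} PNGs;
generation is byte-level deterministic in the seed.

Preprocessing mirrors standard practice for this imagery: bottom-left
anchored 1:1 crop (keeps any bottom-left inset; a 4:5 portrait frame loses
20% from the top), bilinear resize, values in [0, 1]; training augmentation
flips horizontally/vertically with probability 0.5 each and rotates by
Uniform(0°, 90°) with reflect fill (no black corners for the classifier to
exploit).

What the generator does **not** emulate: real mucosal texture statistics,
specular highlights, instrument artifacts, anatomically plausible polyp
morphology, or any intra-class appearance variation beyond the overlay
geometry. Passing tests therefore demonstrate that the pipeline recovers
known, color-and-shape-separable subtypes under controlled conditions; they
do not certify performance on clinical data.

## Problem sizes and degenerate inputs

The bundled experiments use 500 images at 64×64 (320/80/100 split), patch 16
and stride 8 (the 25%-of-side / half-patch ratios), θ = 0.1, σ = 8 — sizes
chosen so a full experiment runs in about two minutes on one CPU core while
reproducing the qualitative regime of the full-scale setup (224×224, patch
64, stride 16).

Degenerate inputs are rejected with typed errors: single-class training
splits, all-zero explanations (weighted image is all-zero — allowed, embeds
normally), K exceeding the number of rows, single-cluster metric requests,
patches larger than the image, smoothing inputs outside [0, 1]. An all-zero
attribution map (constant classifier) normalizes and smooths to the zero
map.

## Known limitations

- The top-left attribution offset noted above.
- Occlusion cost is one classifier call per patch; quadratic in side/stride.
- Silhouette-driven K selection inherits silhouette's bias toward compact,
  well-separated clusters; `KSelection.weak_structure` flags runs whose best
  silhouette is below 0.25.
- With a heavily saturated classifier the normalized explanation amplifies
  probability noise of order 10⁻⁶; the smoothing offset suppresses most but
  not all of it, which is why embedding-level nuisance removal (above) is on
  by default.
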