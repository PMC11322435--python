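# Methods

## Problem setting

Two imaging modalities of the same specimens are paired one-to-one: every
image in modality A has exactly one aligned counterpart in modality B.
Given a query image (or a sub-image patch) in one modality — possibly
rigidly transformed — the task is to retrieve its counterpart from a
repository of the other modality.  The evaluation metric is top-k
retrieval success, Acc@k = (1/N) Σᵢ I_{i,k}, the fraction of queries whose
single correct counterpart appears among the first k retrieved images.
With one correct match per query, precision@k degenerates to {0, 1/k} per
query and coincides with Acc@1 and mAP@1 at k = 1, so Acc@k is the
informative summary.

## Stage I: contrastive representation learning

Two small U-Net encoder-decoders (sharing no weights) map each modality
to a common 1-channel representation space.  Architecture: three levels
(one 3×3 convolution + instance normalization + ReLU per level), 2×2
average pooling, nearest-neighbour upsampling, channel-concatenated skip
connections, and a 1×1 convolution + tanh head, so representation values
are bounded in (−1, 1).  All computation is float32 numpy with manual
backpropagation; given a seed, training is bit-deterministic.

The loss is InfoNCE with a negative-mean-squared-error critic
h(u, v) = −MSE(u, v), temperature τ = 0.5 (default), and M = 46 negatives:
each iteration draws M + 1 = 47 aligned patch pairs at uniform positions;
pair i is the positive for row/column i and the 46 mismatched pairings
within the batch are its negatives.  The loss is symmetrized (averaged
over the A-anchored and B-anchored directions).  With all critic values
equal it evaluates to ln(M + 1) = ln 47 ≈ 3.8501 exactly, which makes the
trace easy to read: values below ln 47 mean the positives are
distinguishable from the negatives.

Two architectural choices deserve explanation:

* **Instance normalization.**  With an unconstrained output, MSE-critic
  InfoNCE rewards growing representation magnitude (negatives push
  apart), and with a bounded output alone, training collapses into the
  constant-representation saddle, where the gradient vanishes identically
  — variance shrinkage is the steepest descent direction from a random
  start.  Per-sample, per-channel standardization after each hidden
  convolution makes the loss invariant to activation scale, which removes
  the collapse mode; the run then descends reliably.
* **tanh head.**  Bounding representations in (−1, 1) keeps the magnitude
  of trained and untrained encoders comparable, so absolute equivariance
  errors (below) can be compared across training states, and gives
  downstream descriptor extraction a fixed input range.

Rotation equivariance is enforced by augmentation: each batch rotates one
randomly chosen side's input patches by a random C4 element and rotates
the produced representations back before the loss.  The equivariance
error of an encoder f for a C4 element r is mean |r(f(x)) − f(r(x))| over
pixels; training with this augmentation reduces it well below the error
of a freshly initialized encoder (measured on held-out synthetic images).

Defaults follow the reference protocol where it states them (τ = 0.5,
46 negatives, 128-px training patches); encoder size, optimizer (Adam,
lr 10⁻³) and step count are configuration keys.  The desk-scale
configuration used throughout the tests and the acceptance script is
6 base channels, 48-px patches, 300 steps, trained on the 10-pair train
split — about four minutes on one CPU.  Patch size and channel count
trade accuracy against CPU time; at these values cross-modal retrieval is
already far above chance, which is what the synthetic study asserts.

## Stage II: features, vocabulary, ranking

Keypoints are placed on a dense regular grid — node (x, y) = (j·sx, i·sy)
with one keypoint per scale s whose s×s support window fits inside the
image (per axis: ⌊(D−s)/spacing⌋ + 1 nodes).  There is no interest-point
detection; the grid fixes locations and scales, and descriptors remain
orientation-normalized, which reconciles dense placement with rotation
invariance.  Intensities are min-max rescaled to [0, 1] per image before
description.

* **SURF-like (64-D).**  Gaussian-derivative responses (smoothed-gradient
  samples — a separable stand-in for Haar box filters) are sampled on an
  n×n grid (default 20×20; desk scale 12×12) rotated to the keypoint's
  dominant orientation (the Gaussian-weighted gradient sum over the
  window), steered into the keypoint frame, and accumulated per 4×4
  subregion as (Σdx, Σ|dx|, Σdy, Σ|dy|), then L2-normalized.  Strength is
  the determinant-of-Hessian response σ⁴|Lxx·Lyy − Lxy²|.
* **SIFT-like (128-D).**  The same sampling machinery feeds 4×4 spatial
  cells × 8 orientation bins of gradient-magnitude histograms (soft
  linear binning over orientation), with the standard 0.2 clamp and
  renormalization.  Strength is the difference-of-Gaussians magnitude
  with 4 steps per octave (k = 2^¼) and base σ = 1.6 at 32-px support.

For 90°-multiple rotations the construction is exactly invariant (up to
float rounding): the gradient field, the orientation estimate, and the
rotated sampling grid all transform consistently, which the tests verify
descriptor-by-descriptor.  Disabling orientation normalization
(`orientation_normalize=False`) deliberately breaks this property and is
used as the non-invariant contrast in the transform-robustness
experiment.

The vocabulary is seeded K-means (k-means++, single init, 100-iteration
cap, tolerance 10⁻⁴; a mini-batch variant with early stopping for pools
where n·K is large, and an optional seeded subsample for clustering) over
the strongest 80% of the pooled repository features — the strength filter
applies only to vocabulary building, never to queries, and queries never
contribute to the vocabulary.  K is clamped to the number of distinct
descriptors.  Encoding is hard assignment to the nearest centroid (ties
to the lowest word index) with L2-normalized counts (TF only, no IDF);
ranking is cosine similarity with ties broken by ascending candidate id.
Featureless images yield an all-zero histogram flagged empty, which
scores 0 against everything.

## Stage III: re-ranking

The top-K initial matches (K ∈ {15, 30}) are re-scored with a freshly
built BoW of the same configuration.  In patch mode each candidate image
is cut into query-sized patches, the new vocabulary is clustered over the
patch pool (K clamped), and an image scores the maximum cosine similarity
over its patches — the query corresponds to one locality, so max is the
natural aggregation.  In full-image mode the new vocabulary is built over
the K images and they are re-ranked directly.  Re-ranking permutes only
the head of the list, so the id set of positions 1..K — and therefore
Acc@K — is exactly conserved.

By default the patch grid is non-overlapping (⌊H/p⌋×⌊W/p⌋ anchored at
multiples of p).  With 512-px images and 256-px center-crop queries that
grid shares at most 25% of its area with the query window, and re-ranking
cannot help; the desk-scale experiments therefore pass
`patch_stride = p/2`, an overlapping grid (9 patches per image) that
bounds query/patch misalignment by p/4 — the alignment geometry an
834/256 benchmark layout has naturally.  Full-image queries against a
patch-level index use minimal equidistant covering tiles
(per axis: n = ⌈(D−p)/p⌉ + 1 positions at round(i·(D−p)/(n−1))) with the
same max aggregation.

## Synthetic paired-modality data

Each scene draws `n_fibers` smoothed random-walk strokes (Gaussian
profile, width `fiber_width_px`) and `n_blobs` Gaussian blobs on a zero
background.  Modality A (dense, brightfield-like) is the inverted blurred
scene plus a smooth background texture field and additive Gaussian noise;
modality B (sparse, SHG-like) is the fiber channel alone with
multiplicative speckle.  Defaults: 512 px, 12 fibers of width 2.5 px,
10 blobs of σ 12 px, noise 0.05.  The generator guarantees the structure
the pipeline must exploit and the gap it must bridge: both renderings
correlate with the latent scene (|r| ≥ 0.3; A negatively, being
inverted), while their mutual raw correlation is weaker than either —
and raw cross-modal retrieval indeed sits at chance.  One master seed
fans out to counter-based child seeds (pair i's seed depends only on
(master, i)), so datasets regenerate bit-identically and adding pairs
never reshuffles existing ones.  Query copies are materialized on disk
under `A_T`/`B_T` modality labels with their transform parameters in the
manifest; split sizes use largest-remainder rounding (ties to the earlier
split).

What the generator does *not* emulate: stain variation, imaging artifacts,
tissue-scale texture statistics, anisotropic point-spread functions, and
the sheer feature density of real histology.  Passing the synthetic study
demonstrates that the pipeline's machinery is correct and that its
qualitative behaviour (monomodal sanity, transform invariance,
cross-modal failure of raw matching, representation-space bridging,
re-ranking gains) reproduces; it does not certify accuracy levels on real
microscopy.

## Desk-scale problem sizes

The synthetic study runs 50 pairs at 512 px (seed 42 in the tests).  Raw
full-image experiments use the SURF-like extractor on the dense (8, 8)
grid at scales (32, 96) with a 2000-word vocabulary — the dense grid is
what makes BoW histograms robust to sub-grid translations.
Representation-space and patch experiments use the (16, 16) grid at the
single scale 128 with 512 words: saturated, coarse representation images
carry their identity at large spatial context, and the larger support
also keeps descriptor counts (and K-means time) small.  Descriptor
sampling is 12×12 per window.  Library defaults remain at the reference
protocol's printed values (spacing (8, 8), scales 32–128, 20,000 words,
20×20 sampling).

## Numerical and degenerate-input conventions

Images are float64 in [0, 1]; integer files are rescaled by their dtype
range (255/65535), never per-image min-max, so no global intensity
information leaks across the query/repository split.  Rotations are
counterclockwise (as displayed) about the exact center ((H−1)/2, (W−1)/2)
with bilinear interpolation and zero fill; coordinates within 10⁻⁹ of a
grid node are snapped so 90°-multiples permute pixels exactly.  The
log-transform preprocessing for high-dynamic-range sparse modalities is
x ↦ log(1 + c·x)/log(1 + c) with c = 255 by default (the exact transform
constant is a configuration key, not a fixed protocol value).  Constant
images produce zero-strength features and empty histograms rather than
errors; K-means clamps K to the distinct-descriptor count; re-ranking
with fewer candidates than K re-ranks what is available and logs it.

## Known limitations

* Training is numpy on one CPU: minutes at desk scale, and far from the
  GPU-scale training real benchmarks need; representation quality here is
  bounded by that budget.
* Instance-norm statistics differ between training patches and full-size
  inference images; representations remain useful but are not
  scale-consistent across very different image sizes.
* Hard assignment into the vocabulary makes histograms sensitive to
  descriptor perturbations; the dense grid compensates, soft assignment
  and IDF weighting are deliberately out of scope.
* The rigid-transform model covers rotation and translation only — no
  scaling, shear, or elastic deformation.
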