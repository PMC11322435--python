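# xmir — cross-modality (sub-)image retrieval

`xmir` is a reverse image search system for paired imaging modalities that
look nothing alike — the motivating case is brightfield (BF) histology
against second-harmonic-generation (SHG) collagen imaging, where each
query image in one modality has exactly one correct counterpart in a
repository of the other modality (instance-level retrieval).  Querying
such repositories directly fails: the two modalities share structure but
almost no appearance.

The pipeline has three stages:

1. **Shared representation space.**  Two U-Net encoders (no shared
   weights), one per modality, are trained on aligned image pairs with an
   InfoNCE contrastive loss whose critic is the negative mean squared
   error between the produced 1-channel representation images,

   L = −log [ e^{h(x,y)/τ} / ( e^{h(x,y)/τ} + Σ_j e^{h(x,y'_j)/τ} ) ],
   h(u,v) = −MSE(u,v),

   symmetrized over both modality directions, with temperature τ = 0.5 and
   46 negative pairs per iteration.  During training one side of each
   batch is rotated by a random C4 element ({0°, 90°, 180°, 270°}) and the
   representation is rotated back before the loss, which enforces
   rotational equivariance of the learned maps.
2. **Bag of visual words.**  Sparse scale- and rotation-invariant local
   descriptors (SURF-like 64-D or SIFT-like 128-D) are extracted on a
   dense grid (default spacing (8, 8), patch scales 32–128); a K-means
   vocabulary (default 20,000 words) is clustered from the strongest 80%
   of the pooled repository features; each image becomes an L2-normalized
   word histogram, ranked by cosine similarity (Acc@k = fraction of
   queries whose correct counterpart appears in the first k results).
3. **Re-ranking.**  The top-K matches (K = 15 or 30) are re-scored with a
   fresh BoW built over query-sized patches of those K images (or over the
   K full images for full-image search).

Because the real BF/SHG benchmark needs external downloads and GPU-scale
training, the package ships a first-class synthetic generator
(`xmir.synthetic`) that emulates its statistical structure: latent scenes
of curvilinear fibers and blobs rendered into a dense texture-like
modality A and a sparse structure-like modality B, with rigidly
transformed query copies (rotations up to ±30°, translations up to
±100 px) and 256-px patch queries.  The whole pipeline is testable on a
single CPU.

## Worked example

```python
import numpy as np
from xmir import (SceneParams, generate_pairs, TrainConfig, train_comir,
                  compute_representation, RetrievalIndex, ExtractorConfig,
                  evaluate_direction)

pairs = generate_pairs(50, params=SceneParams(size=512), master_seed=42)
ids = [a.id for a, _ in pairs]

# Stage I: desk-scale contrastive training on the first 10 pairs
enc, trace = train_comir(pairs[:10],
                         TrainConfig(patch_px=48, steps=300, seed=1,
                                     base_channels=6))
print(f"loss {np.mean(trace[:10]):.2f} -> {np.mean(trace[-10:]):.2f}")

# Stage II: index modality-A representations, query with modality-B ones
cfg = ExtractorConfig(kind="surf_like", grid_spacing=(16, 16),
                      scales=(128,), n_samples=12)
reps_a = [compute_representation(enc.encoder_A, a) for a, _ in pairs]
reps_b = [compute_representation(enc.encoder_B, b) for _, b in pairs]
index = RetrievalIndex(extractor=cfg, vocab_size=512, seed=0).build(reps_a)
res = evaluate_direction(list(zip(ids, reps_b)), index, {p: p for p in ids})
print(f"cross-modal Acc@1={res.acc[1]:.2f} Acc@10={res.acc[10]:.2f}")
```

Output on this configuration:

```
loss 3.82 -> 2.29
cross-modal Acc@1=0.72 Acc@10=0.98
```

The training loss falls well below ln 47 ≈ 3.85 (the value at which
positives and negatives are indistinguishable), and cross-modal retrieval
lands the correct counterpart first for 72% of queries (chance is 2%) —
the same queries on the raw images score at chance.

A CLI mirrors the library: `xmir synth`, `xmir train-comir`, `xmir embed`,
`xmir build-index`, `xmir query`, `xmir evaluate`.

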