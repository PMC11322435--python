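"""Bag-of-visual-words vocabulary, histogram encoding, ranking, re-ranking.

The vocabulary is a K-means clustering of repository descriptors (built on
the strongest 80% of pooled features, never on queries); each image is
encoded as an L2-normalized histogram of hard word assignments; ranking is
by cosine similarity with deterministic ties broken by ascending candidate
id.  Sub-image queries are supported by patch splitting (non-overlapping,
for building the re-ranking database) and minimal equidistant tiling (for
covering a full image with query-sized tiles).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans, MiniBatchKMeans

from .features import ExtractorConfig, FeatureSet, detect_and_describe, filter_strongest

logger = logging.getLogger(__name__)

__all__ = [
    "Vocabulary",
    "BowHistogram",
    "RankedList",
    "build_vocabulary",
    "encode_histogram",
    "cosine_rank",
    "tile_query_sized",
    "split_nonoverlapping",
    "RetrievalIndex",
]

# above this assignment-cost product, clustering switches to minibatch
_MINIBATCH_THRESHOLD = 2_000_000


@dataclass
class Vocabulary:
    """K cluster centroids in descriptor space (the visual words)."""

    centroids: np.ndarray
    requested_k: int

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float32)
        if self.centroids.ndim != 2 or len(self.centroids) < 1:
            raise ValueError("centroids must be a non-empty (K, L) matrix")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    @property
    def k(self) -> int:
        return len(self.centroids)

    @property
    def descriptor_length(self) -> int:
        return self.centroids.shape[1]


@dataclass
class BowHistogram:
    """Unit-L2 word-count vector; all-zero and flagged if the source had
    no features."""

    vector: np.ndarray
    image_id: str
    empty: bool = False

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)


@dataclass
class RankedList:
    """Ordered (candidate id, similarity) pairs for one query."""

    query_id: str
    entries: List[Tuple[str, float]]

    def ids(self) -> List[str]:
        return [e[0] for e in self.entries]

    def rank_of(self, candidate_id: str) -> Optional[int]:
        """1-based rank, or None if absent."""
        for i, (cid, _) in enumerate(self.entries, start=1):
            if cid == candidate_id:
                return i
        return None


def build_vocabulary(
    feature_sets: Sequence[FeatureSet],
    k: int,
    seed: int = 0,
    max_train_descriptors: Optional[int] = None,
) -> Vocabulary:
    """Seeded K-means over the pooled descriptors, K clamped to the number
    of distinct descriptors.

    ``max_train_descriptors`` fits the clustering on a seeded random
    subsample of the pool (a standard vocabulary-building shortcut for
    large repositories); assignment downstream still uses all descriptors.
    """
    pools = [fs.descriptors for fs in feature_sets if len(fs) > 0]
    if not pools:
        raise ValueError("no features to cluster")
    desc = np.concatenate(pools, axis=0).astype(np.float32)
    if max_train_descriptors is not None and len(desc) > max_train_descriptors:
        sel = np.random.default_rng(seed).choice(
            len(desc), size=max_train_descriptors, replace=False
        )
        desc = desc[np.sort(sel)]
    if np.all(desc == desc[0]):
        n_distinct = 1
    elif len(desc) >= 16 * k:
        # the clamp cannot realistically bind; skip the costly distinct count
        n_distinct = len(desc)
    else:
        n_distinct = len(np.unique(desc, axis=0))
    k_eff = min(k, n_distinct)
    if k_eff < k:
        logger.info("vocabulary clamped from %d to %d distinct descriptors", k, k_eff)
    if len(desc) * k_eff > _MINIBATCH_THRESHOLD and k_eff > 1:
        km = MiniBatchKMeans(
            n_clusters=k_eff,
            init="k-means++",
            n_init=1,
            max_iter=20,
            batch_size=4096,
            max_no_improvement=10,
            tol=1e-4,
            random_state=seed,
        )
    else:
        km = KMeans(
            n_clusters=k_eff,
            init="k-means++",
            n_init=1,
            max_iter=100,
            tol=1e-4,
            random_state=seed,
        )
    km.fit(desc)
    return Vocabulary(centroids=km.cluster_centers_.astype(np.float32), requested_k=k)


def encode_histogram(features: FeatureSet, vocab: Vocabulary) -> BowHistogram:
    """Hard-assign each descriptor to its nearest word (ties to the lowest
    index) and L2-normalize the counts."""
    if len(features) == 0:
        return BowHistogram(
            vector=np.zeros(vocab.k), image_id=features.image_id, empty=True
        )
    if features.descriptors.shape[1] != vocab.descriptor_length:
        raise ValueError(
            f"descriptor length {features.descriptors.shape[1]} does not match "
            f"vocabulary length {vocab.descriptor_length}"
        )
    counts = np.zeros(vocab.k, dtype=np.float64)
    desc = features.descriptors.astype(np.float32)
    cent = vocab.centroids
    chunk = max(1, 2_000_000 // max(1, vocab.k))
    for i in range(0, len(desc), chunk):
        d = cdist(desc[i : i + chunk], cent, metric="sqeuclidean")
        counts += np.bincount(np.argmin(d, axis=1), minlength=vocab.k)
    norm = np.linalg.norm(counts)
    return BowHistogram(vector=counts / norm, image_id=features.image_id, empty=False)


def cosine_rank(query: BowHistogram, repo: Sequence[BowHistogram]) -> RankedList:
    """Full cosine-similarity ordering of the repository for one query.

    Histograms are unit-norm, so similarity is the dot product; empty
    (all-zero) histograms contribute similarity 0.  Ties are broken by
    ascending candidate id.
    """
    for h in repo:
        if h.vector.shape != query.vector.shape:
            raise ValueError("histogram length mismatch between query and repository")
    scores = [
        (hist.image_id, 0.0 if (query.empty or hist.empty)
         else float(query.vector @ hist.vector))
        for hist in repo
    ]
    scores.sort(key=lambda e: (-e[1], e[0]))
    return RankedList(query_id=query.image_id, entries=scores)


def _tile_positions(extent: int, patch: int) -> List[int]:
    if patch == extent:
        return [0]
    n = math.ceil((extent - patch) / patch) + 1
    return [int(math.floor(i * (extent - patch) / (n - 1) + 0.5)) for i in range(n)]


def tile_query_sized(img, patch_px: int) -> List[Tuple[Tuple[int, int], np.ndarray]]:
    """Minimal number of equidistantly placed query-sized tiles fully
    covering the image; returns ((row, col) offset, tile) row-major."""
    gray = img.gray() if hasattr(img, "gray") else np.asarray(img)
    h, w = gray.shape[:2]
    if patch_px > min(h, w):
        raise ValueError(f"patch size {patch_px} exceeds image extent {h}x{w}")
    tiles = []
    for r in _tile_positions(h, patch_px):
        for c in _tile_positions(w, patch_px):
            tiles.append(((r, c), gray[r : r + patch_px, c : c + patch_px]))
    return tiles


def split_nonoverlapping(
    img, patch_px: int, stride: Optional[int] = None
) -> List[Tuple[Tuple[int, int], np.ndarray]]:
    """Disjoint patches anchored at multiples of p (the right/bottom
    remainder strip is dropped): floor(H/p) x floor(W/p) patches.

    A ``stride`` smaller than ``patch_px`` yields an overlapping grid
    (anchors at multiples of the stride, windows fully inside the image),
    which bounds the misalignment between an arbitrary query window and
    its best-covered patch by stride/2.
    """
    gray = img.gray() if hasattr(img, "gray") else np.asarray(img)
    h, w = gray.shape[:2]
    if patch_px > min(h, w):
        raise ValueError(f"patch size {patch_px} exceeds image extent {h}x{w}")
    step = patch_px if stride is None else int(stride)
    if step < 1:
        raise ValueError("stride must be >= 1")
    patches = []
    for r in range(0, h - patch_px + 1, step):
        for c in range(0, w - patch_px + 1, step):
            patches.append(((r, c), gray[r : r + patch_px, c : c + patch_px]))
    return patches


class _NamedPatch:
    """Lightweight image wrapper so patches flow through feature extraction."""

    def __init__(self, patch_id: str, pixels: np.ndarray) -> None:
        self.id = patch_id
        self.pixels = np.asarray(pixels, dtype=np.float64)

    def gray(self) -> np.ndarray:
        return self.pixels


class RetrievalIndex:
    """Searchable repository: vocabulary + per-image histograms.

    Built over a list of images (raw images or learned representations -
    anything exposing ``id`` and ``gray()``).  The vocabulary is clustered
    from the strongest ``strongest_fraction`` of the pooled repository
    features; query features are never filtered and never contribute to
    the vocabulary.
    """

    def __init__(
        self,
        extractor: ExtractorConfig = ExtractorConfig(),
        vocab_size: int = 20_000,
        seed: int = 0,
        strongest_fraction: float = 0.8,
        max_train_descriptors: Optional[int] = None,
    ) -> None:
        self.extractor = extractor
        self.vocab_size = vocab_size
        self.seed = seed
        self.strongest_fraction = strongest_fraction
        self.max_train_descriptors = max_train_descriptors
        self.vocabulary: Optional[Vocabulary] = None
        self.histograms: List[BowHistogram] = []
        self.ids: List[str] = []
        self._images: Dict[str, np.ndarray] = {}
        self._patch_feature_cache: Dict[Tuple, FeatureSet] = {}

    def build(self, images: Sequence) -> "RetrievalIndex":
        feature_sets = []
        self.ids = []
        self._images = {}
        for img in images:
            self.ids.append(img.id)
            self._images[img.id] = np.asarray(img.gray(), dtype=np.float32)
            feature_sets.append(detect_and_describe(img, self.extractor))
        filtered = filter_strongest(feature_sets, self.strongest_fraction)
        self.vocabulary = build_vocabulary(
            filtered, self.vocab_size, seed=self.seed,
            max_train_descriptors=self.max_train_descriptors,
        )
        self.histograms = [encode_histogram(fs, self.vocabulary) for fs in feature_sets]
        self._patch_feature_cache = {}
        return self

    def _require_built(self) -> None:
        if self.vocabulary is None:
            raise RuntimeError("index not built; call build() first")

    def query_histogram(self, img) -> BowHistogram:
        self._require_built()
        fs = detect_and_describe(img, self.extractor)
        return encode_histogram(fs, self.vocabulary)

    def retrieve(self, query, tile_patch_px: Optional[int] = None) -> RankedList:
        """Rank the whole repository for a query image or patch.

        With ``tile_patch_px`` set and a query larger than that size, the
        query is cut into minimal covering tiles and each candidate scores
        the maximum similarity over tiles.
        """
        self._require_built()
        gray = query.gray() if hasattr(query, "gray") else np.asarray(query)
        qid = getattr(query, "id", "query")
        if tile_patch_px is not None and min(gray.shape) > tile_patch_px:
            best: Dict[str, float] = {}
            for (r, c), tile in tile_query_sized(query, tile_patch_px):
                hist = self.query_histogram(_NamedPatch(f"{qid}@{r},{c}", tile))
                ranked = cosine_rank(hist, self.histograms)
                for cid, score in ranked.entries:
                    if score > best.get(cid, -np.inf):
                        best[cid] = score
            entries = sorted(best.items(), key=lambda e: (-e[1], e[0]))
            return RankedList(query_id=qid, entries=entries)
        hist = self.query_histogram(query)
        ranked = cosine_rank(hist, self.histograms)
        ranked.query_id = qid
        return ranked

    def rerank(
        self,
        query,
        initial: RankedList,
        top_k: int = 15,
        mode: str = "patch",
        patch_stride: Optional[int] = None,
    ) -> RankedList:
        """Re-rank the top-k initial matches with a freshly built BoW.

        ``patch`` mode cuts each of the top-k images into non-overlapping
        query-sized patches, builds a new vocabulary over the patch pool
        (same configuration, K clamped to the pool size), and scores each
        image by the maximum similarity over its patches (``patch_stride``
        below the patch size switches to an overlapping grid so that some
        database patch stays aligned with any query window).  ``full_image``
        mode builds the new vocabulary over the top-k images and re-ranks
        them directly.  Ids outside the top-k keep their original relative
        order after the re-ranked block; the id set of positions 1..top_k
        is conserved.
        """
        self._require_built()
        if mode not in ("patch", "full_image"):
            raise ValueError(f"unknown rerank mode {mode!r}")
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        if len(initial.entries) < top_k:
            logger.warning(
                "re-ranking over %d available candidates (top_k=%d requested)",
                len(initial.entries), top_k,
            )
            top_k = len(initial.entries)
        head_ids = [cid for cid, _ in initial.entries[:top_k]]
        tail = initial.entries[top_k:]
        gray = query.gray() if hasattr(query, "gray") else np.asarray(query)
        qid = getattr(query, "id", "query")
        patch_px = min(gray.shape[:2])

        if mode == "full_image":
            sets = [
                detect_and_describe(
                    _NamedPatch(cid, self._images[cid]), self.extractor
                )
                for cid in head_ids
            ]
            pooled = filter_strongest(sets, self.strongest_fraction)
            vocab = build_vocabulary(
                pooled, self.vocab_size, seed=self.seed,
                max_train_descriptors=self.max_train_descriptors,
            )
            q_hist = encode_histogram(
                detect_and_describe(query, self.extractor), vocab
            )
            hists = [encode_histogram(fs, vocab) for fs in sets]
            scored = {h.image_id: (0.0 if (q_hist.empty or h.empty)
                                   else float(q_hist.vector @ h.vector))
                      for h in hists}
        else:
            patch_sets: List[FeatureSet] = []
            owner: List[str] = []
            for cid in head_ids:
                for (r, c), patch in split_nonoverlapping(
                    self._images[cid], patch_px, stride=patch_stride
                ):
                    key = (cid, r, c, patch_px, self.extractor)
                    fs = self._patch_feature_cache.get(key)
                    if fs is None:
                        fs = detect_and_describe(
                            _NamedPatch(f"{cid}@{r},{c}", patch), self.extractor
                        )
                        self._patch_feature_cache[key] = fs
                    patch_sets.append(fs)
                    owner.append(cid)
            pooled = filter_strongest(patch_sets, self.strongest_fraction)
            vocab = build_vocabulary(
                pooled, self.vocab_size, seed=self.seed,
                max_train_descriptors=self.max_train_descriptors,
            )
            q_hist = encode_histogram(
                detect_and_describe(query, self.extractor), vocab
            )
            scored = {cid: 0.0 for cid in head_ids}
            for cid, fs in zip(owner, patch_sets):
                h = encode_histogram(fs, vocab)
                sim = 0.0 if (q_hist.empty or h.empty) else float(
                    q_hist.vector @ h.vector
                )
                if sim > scored[cid]:
                    scored[cid] = sim

        head = sorted(scored.items(), key=lambda e: (-e[1], e[0]))
        return RankedList(query_id=qid, entries=head + tail)
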