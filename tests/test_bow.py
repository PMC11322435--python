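import numpy as np
import pytest

from xmir.bow import (
    BowHistogram,
    RetrievalIndex,
    Vocabulary,
    build_vocabulary,
    cosine_rank,
    encode_histogram,
    split_nonoverlapping,
    tile_query_sized,
)
from xmir.features import ExtractorConfig, FeatureSet
from xmir.synthetic import SceneParams, generate_pairs

LIGHT = ExtractorConfig(kind="surf_like", grid_spacing=(16, 16), scales=(32,), n_samples=12)


def _feature_set(descriptors, image_id="img"):
    descriptors = np.asarray(descriptors, dtype=np.float32)
    kps = np.tile([0.0, 0.0, 32.0, 1.0], (len(descriptors), 1))
    return FeatureSet(image_id, kps, descriptors)


class TestVocabulary:
    def test_exact_clustering_when_k_equals_distinct(self):
        desc = np.eye(5, 8, dtype=np.float32)
        vocab = build_vocabulary([_feature_set(desc)], 5, seed=0)
        assert vocab.k == 5
        # centroids equal the descriptors up to permutation -> zero inertia
        dists = ((desc[:, None, :] - vocab.centroids[None]) ** 2).sum(-1)
        assert dists.min(axis=1).sum() == pytest.approx(0.0, abs=1e-12)

    def test_single_cluster_is_mean(self):
        desc = np.array([[0, 0], [2, 4], [4, 2]], dtype=np.float32)
        vocab = build_vocabulary([_feature_set(desc)], 1, seed=0)
        assert np.allclose(vocab.centroids[0], [2, 2])

    def test_k_clamped_to_distinct_count(self):
        desc = np.repeat(np.eye(3, 8, dtype=np.float32), 4, axis=0)
        vocab = build_vocabulary([_feature_set(desc)], 20000, seed=0)
        assert vocab.k == 3
        assert vocab.requested_k == 20000

    def test_empty_pool_rejected(self):
        empty = FeatureSet("e", np.empty((0, 4)), np.empty((0, 8), np.float32))
        with pytest.raises(ValueError, match="no features"):
            build_vocabulary([empty], 5)

    def test_seeded_subsample_is_deterministic(self):
        rng = np.random.default_rng(0)
        desc = rng.random((500, 8)).astype(np.float32)
        v1 = build_vocabulary([_feature_set(desc)], 4, seed=1, max_train_descriptors=100)
        v2 = build_vocabulary([_feature_set(desc)], 4, seed=1, max_train_descriptors=100)
        assert np.array_equal(v1.centroids, v2.centroids)


class TestEncodeHistogram:
    VOCAB = Vocabulary(centroids=np.eye(4, 8, dtype=np.float32), requested_k=4)

    def test_single_word_assignment(self):
        desc = np.tile(self.VOCAB.centroids[3], (8, 1))
        hist = encode_histogram(_feature_set(desc), self.VOCAB)
        assert np.allclose(hist.vector, [0, 0, 0, 1])

    def test_two_word_normalization(self):
        desc = self.VOCAB.centroids[:2]
        hist = encode_histogram(_feature_set(desc), self.VOCAB)
        assert np.allclose(hist.vector, [1 / np.sqrt(2), 1 / np.sqrt(2), 0, 0])

    def test_empty_features_give_flagged_zero_histogram(self):
        empty = FeatureSet("e", np.empty((0, 4)), np.empty((0, 8), np.float32))
        hist = encode_histogram(empty, self.VOCAB)
        assert hist.empty and not hist.vector.any()

    def test_tie_assigned_to_lowest_word_index(self):
        # equidistant from words 1 and 2
        desc = (self.VOCAB.centroids[1] + self.VOCAB.centroids[2]) / 2
        hist = encode_histogram(_feature_set(desc[None]), self.VOCAB)
        assert hist.vector[1] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            encode_histogram(_feature_set(np.ones((2, 5))), self.VOCAB)


class TestCosineRank:
    def test_exact_self_match_ranks_first_with_unit_score(self):
        h = BowHistogram(np.array([0.6, 0.8]), "q")
        repo = [BowHistogram(np.array([0.8, 0.6]), "a"),
                BowHistogram(np.array([0.6, 0.8]), "b")]
        ranked = cosine_rank(h, repo)
        assert ranked.entries[0] == ("b", pytest.approx(1.0))

    def test_disjoint_supports_score_zero(self):
        h = BowHistogram(np.array([1.0, 0.0]), "q")
        ranked = cosine_rank(h, [BowHistogram(np.array([0.0, 1.0]), "a")])
        assert ranked.entries[0][1] == 0.0

    def test_hand_computed_ordering(self):
        q = BowHistogram(np.array([1, 1, 0]) / np.sqrt(2), "q")
        repo = [BowHistogram(np.array([1, 0, 1]) / np.sqrt(2), "r1"),
                BowHistogram(np.array([0, 1, 0.0]), "r2")]
        ranked = cosine_rank(q, repo)
        assert ranked.ids() == ["r2", "r1"]
        assert ranked.entries[0][1] == pytest.approx(1 / np.sqrt(2))
        assert ranked.entries[1][1] == pytest.approx(0.5)

    def test_ties_broken_by_ascending_id(self):
        q = BowHistogram(np.array([1.0, 0.0]), "q")
        repo = [BowHistogram(np.array([1.0, 0.0]), f"r{i}") for i in (3, 1, 2)]
        assert cosine_rank(q, repo).ids() == ["r1", "r2", "r3"]

    def test_empty_histograms_score_zero(self):
        q = BowHistogram(np.zeros(2), "q", empty=True)
        ranked = cosine_rank(q, [BowHistogram(np.array([1.0, 0]), "a")])
        assert ranked.entries[0][1] == 0.0

    def test_brute_force_oracle_equivalence(self):
        """cosine_rank must equal an explicit similarity sort (incl. ties)."""
        rng = np.random.default_rng(7)
        repo = []
        for i in range(100):
            v = rng.integers(0, 3, size=16).astype(float)
            n = np.linalg.norm(v)
            repo.append(
                BowHistogram(v / n if n else v, f"id{i:03d}", empty=not n)
            )
        q = repo[17]
        expected = sorted(
            (
                (h.image_id, 0.0 if (h.empty or q.empty)
                 else float(np.dot(q.vector, h.vector)))
                for h in repo
            ),
            key=lambda e: (-e[1], e[0]),
        )
        assert cosine_rank(q, repo).entries == expected


class TestTiling:
    def test_benchmark_axis_positions_and_coverage(self):
        img = np.zeros((834, 834))
        tiles = tile_query_sized(img, 256)
        rows = sorted({r for (r, c), _ in tiles})
        assert rows == [0, 193, 385, 578]
        assert len(tiles) == 16
        covered = np.zeros((834, 834), bool)
        for (r, c), _ in tiles:
            covered[r : r + 256, c : c + 256] = True
        assert covered.all()

    def test_minimality_removing_any_position_breaks_coverage(self):
        positions = [0, 193, 385, 578]
        for drop in range(4):
            covered = np.zeros(834, bool)
            for i, p in enumerate(positions):
                if i != drop:
                    covered[p : p + 256] = True
            assert not covered.all()

    def test_exact_fit_single_tile(self):
        tiles = tile_query_sized(np.zeros((256, 256)), 256)
        assert len(tiles) == 1 and tiles[0][0] == (0, 0)

    def test_divisible_case_non_overlapping(self):
        tiles = tile_query_sized(np.zeros((512, 512)), 256)
        assert sorted({r for (r, c), _ in tiles}) == [0, 256]
        assert len(tiles) == 4

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            tile_query_sized(np.zeros((100, 100)), 256)


class TestSplitNonoverlapping:
    def test_benchmark_grid_drops_remainder(self):
        patches = split_nonoverlapping(np.zeros((834, 834)), 256)
        assert len(patches) == 9
        anchors = {a for a, _ in patches}
        assert anchors == {(r, c) for r in (0, 256, 512) for c in (0, 256, 512)}

    def test_disjointness(self):
        img = np.zeros((834, 834))
        counts = np.zeros_like(img)
        for (r, c), _ in split_nonoverlapping(img, 256):
            counts[r : r + 256, c : c + 256] += 1
        assert counts.max() == 1

    def test_divisible_and_identity_cases(self):
        assert len(split_nonoverlapping(np.zeros((512, 512)), 256)) == 4
        patches = split_nonoverlapping(np.zeros((256, 256)), 256)
        assert len(patches) == 1

    def test_half_stride_gives_overlapping_grid(self):
        patches = split_nonoverlapping(np.zeros((512, 512)), 256, stride=128)
        assert len(patches) == 9


@pytest.fixture(scope="module")
def small_index():
    pairs = generate_pairs(
        6, params=SceneParams(size=128, n_fibers=6, n_blobs=3), master_seed=9
    )
    imgs = [a for a, _ in pairs]
    index = RetrievalIndex(extractor=LIGHT, vocab_size=64, seed=0).build(imgs)
    return index, imgs


class TestRetrievalIndex:
    def test_uninitialized_index_rejected(self):
        idx = RetrievalIndex(extractor=LIGHT)
        with pytest.raises(RuntimeError, match="not built"):
            idx.retrieve(np.zeros((64, 64)))

    def test_repo_query_is_exact_self_match(self, small_index):
        index, imgs = small_index
        ranked = index.retrieve(imgs[2])
        assert ranked.entries[0][0] == imgs[2].id
        assert ranked.entries[0][1] == pytest.approx(1.0)

    def test_full_ordering_returned(self, small_index):
        index, imgs = small_index
        assert len(index.retrieve(imgs[0]).entries) == 6

    def test_rerank_conserves_head_membership(self, small_index):
        index, imgs = small_index
        from xmir.image_io import crop_center

        query = crop_center(imgs[3], 64)
        initial = index.retrieve(query)
        for mode in ("patch", "full_image"):
            rr = index.rerank(query, initial, top_k=4, mode=mode)
            assert set(rr.ids()[:4]) == set(initial.ids()[:4])
            assert rr.ids()[4:] == initial.ids()[4:]

    def test_rerank_top1_is_identity(self, small_index):
        index, imgs = small_index
        initial = index.retrieve(imgs[1])
        rr = index.rerank(imgs[1], initial, top_k=1, mode="full_image")
        assert rr.ids()[0] == initial.ids()[0]

    def test_rerank_with_fewer_candidates_than_top_k(self, small_index, caplog):
        index, imgs = small_index
        initial = index.retrieve(imgs[0])
        rr = index.rerank(imgs[0], initial, top_k=50, mode="full_image")
        assert set(rr.ids()) == set(initial.ids())

    def test_tiled_retrieval_of_full_image_in_patch_terms(self, small_index):
        index, imgs = small_index
        ranked = index.retrieve(imgs[4], tile_patch_px=64)
        assert imgs[4].id in ranked.ids()[:3]
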