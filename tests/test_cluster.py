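"""Embedding construction, k-means wrapper and agreement metrics."""

import itertools

import numpy as np
import pytest
from sklearn import metrics as skm

from gstrpca import (
    DomainError,
    ami,
    ari,
    build_embedding,
    clustering_accuracy,
    evaluate_clustering,
    kmeans_cells,
    make_irregular,
    nmi,
)
from gstrpca.tensor import zeros_like


def random_pair(rng, n=30, ka=4, kb=5):
    return rng.integers(0, ka, n), rng.integers(0, kb, n)


class TestEmbedding:
    def make_le(self, rng):
        L = make_irregular([rng.normal(size=(3, 7)), rng.normal(size=(5, 7))])
        E = make_irregular([rng.normal(size=(3, 7)), rng.normal(size=(5, 7))])
        return L, E

    def test_alpha_zero_uses_low_rank_only(self, rng):
        L, E = self.make_le(rng)
        emb = build_embedding(L, E, alpha=0.0)
        np.testing.assert_array_equal(emb, np.vstack(L.slices).T)

    def test_zero_sparse_makes_alpha_irrelevant(self, rng):
        L, _ = self.make_le(rng)
        z = zeros_like(L)
        np.testing.assert_array_equal(
            build_embedding(L, z, alpha=0.2), build_embedding(L, z, alpha=0.9)
        )

    def test_matches_entrywise_then_concat_oracle(self, rng):
        L, E = self.make_le(rng)
        emb = build_embedding(L, E, alpha=0.5)
        expected = np.vstack(
            [l + 0.5 * e for l, e in zip(L.slices, E.slices)]
        ).T
        np.testing.assert_allclose(emb, expected, rtol=1e-14)
        assert emb.shape == (7, 8)  # cells x total features

    def test_rank_d_projection_shape(self, rng):
        L, E = self.make_le(rng)
        emb = build_embedding(L, E, d=2)
        assert emb.shape == (7, 2)
        with pytest.raises(DomainError):
            build_embedding(L, E, d=100)


class TestKMeans:
    def test_separated_clouds_partition_perfectly(self, rng):
        a = rng.normal(size=(20, 2))
        b = rng.normal(size=(20, 2)) + 50.0
        emb = np.vstack([a, b])
        truth = np.repeat([0, 1], 20)
        pred = kmeans_cells(emb, 2, seed=0)
        assert ari(truth, pred) == pytest.approx(1.0)

    def test_k_equals_n_gives_singletons(self, rng):
        emb = rng.normal(size=(6, 3)) * 10
        pred = kmeans_cells(emb, 6, seed=0)
        assert len(np.unique(pred)) == 6

    def test_deterministic_given_seed(self, rng):
        emb = rng.normal(size=(40, 5))
        p1 = kmeans_cells(emb, 3, seed=11)
        p2 = kmeans_cells(emb, 3, seed=11)
        np.testing.assert_array_equal(p1, p2)

    def test_k_out_of_range(self, rng):
        emb = rng.normal(size=(5, 2))
        for k in (1, 6):
            with pytest.raises(DomainError):
                kmeans_cells(emb, k)


class TestAccuracy:
    def test_identical_labelings(self):
        assert clustering_accuracy([0, 1, 1, 2], [0, 1, 1, 2]) == 1.0

    def test_invariant_to_renaming(self):
        truth = [0, 0, 1, 1, 2, 2]
        renamed = [2, 2, 0, 0, 1, 1]
        assert clustering_accuracy(truth, renamed) == 1.0

    def test_matches_exhaustive_permutation_oracle(self, rng):
        for _ in range(20):
            truth, pred = random_pair(rng, n=25, ka=4, kb=4)
            best = 0.0
            for perm in itertools.permutations(range(4)):
                mapped = np.array([perm[p] for p in pred])
                best = max(best, np.mean(mapped == truth))
            assert clustering_accuracy(truth, pred) == pytest.approx(best)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            clustering_accuracy([0, 1], [0, 1, 2])


class TestInformationMetrics:
    def test_perfect_agreement_scores_one(self):
        labels = [0, 1, 1, 2, 2, 2]
        for metric in (nmi, ari, ami):
            assert metric(labels, labels) == pytest.approx(1.0)

    def test_one_cluster_vs_many_ari_zero(self):
        assert ari([0, 1, 2, 3], [0, 0, 0, 0]) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "mine,ref",
        [
            # geometric mean matches the I/sqrt(H_U H_V) definition
            (
                nmi,
                lambda a, b: skm.normalized_mutual_info_score(
                    a, b, average_method="geometric"
                ),
            ),
            (ari, skm.adjusted_rand_score),
            (ami, skm.adjusted_mutual_info_score),
        ],
    )
    def test_matches_reference_implementation(self, mine, ref, rng):
        for _ in range(30):
            truth, pred = random_pair(rng)
            assert mine(truth, pred) == pytest.approx(ref(truth, pred), abs=1e-10)

    def test_invariant_to_renaming_both_sides(self, rng):
        truth, pred = random_pair(rng)
        t2 = 7 - truth  # relabel
        p2 = np.array(["c%d" % p for p in pred])  # string relabel
        for metric in (nmi, ari, ami):
            assert metric(truth, pred) == pytest.approx(metric(t2, p2), abs=1e-12)


class TestEvaluate:
    def test_end_to_end_on_separable_tensor(self, rng):
        # two cell groups with distinct mean profiles in both slices
        truth = np.repeat([0, 1], 10)
        shift = np.where(truth == 1, 30.0, 0.0)
        L = make_irregular(
            [rng.normal(size=(4, 20)) + shift, rng.normal(size=(9, 20)) + shift]
        )
        res = evaluate_clustering(L, zeros_like(L), truth, seed=0)
        assert res.k == 2
        assert res.metrics["acc"] == 1.0
        assert res.metrics["ari"] == pytest.approx(1.0)
        assert set(res.metrics) == {"acc", "nmi", "ari", "ami"}
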