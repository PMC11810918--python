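"""Embedding, density clustering, silhouette, phenotype labeling."""

import numpy as np
import pandas as pd
import pytest

from mhpheno.clustering import (
    NOISE,
    EmbeddingConfig,
    PhenotypeCluster,
    adjusted_rand,
    cluster_embedding,
    embed_scores,
    evaluate_silhouette,
    label_phenotypes,
)


def two_blob_scores(rng, n=200, gap=30):
    """Two well-separated synthetic score blobs (n each)."""
    a = rng.normal([5, 3, 20], 1.5, size=(n, 3))
    b = rng.normal([5 + gap, 3 + gap, 20 + gap], 1.5, size=(n, 3))
    return np.vstack([a, b])


class TestEmbedScores:
    def test_same_seed_identical(self, rng):
        X = two_blob_scores(rng, n=60)
        cfg = EmbeddingConfig(seed=4)
        assert np.array_equal(embed_scores(X, cfg), embed_scores(X, cfg))

    def test_identical_rows_collapse_without_dither(self):
        X = np.tile([7.0, 3.0, 21.0], (50, 1))
        emb = embed_scores(X, EmbeddingConfig(seed=1, dither=0.0))
        assert emb.std(axis=0).max() < 1e-3

    def test_two_blobs_separate(self, rng):
        X = two_blob_scores(rng)
        emb = embed_scores(X, EmbeddingConfig(seed=2))
        a, b = emb[:200], emb[200:]
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        within = max(a.std(), b.std())
        assert between > 3 * within

    def test_too_small_n_raises(self, rng):
        with pytest.raises(ValueError, match="too small"):
            embed_scores(rng.normal(size=(5, 3)), EmbeddingConfig(n_neighbors=10))

    def test_missing_values_rejected(self):
        X = np.full((40, 3), np.nan)
        with pytest.raises(ValueError, match="missing"):
            embed_scores(X, EmbeddingConfig())


class TestClusterEmbedding:
    def test_two_gaussian_blobs_found(self, rng):
        emb = np.vstack(
            [rng.normal(0, 1, (200, 2)), rng.normal(20, 1, (200, 2))]
        )
        labels = cluster_embedding(emb, min_cluster_size=11, min_samples=11)
        real = labels[labels != NOISE]
        assert len(np.unique(real)) == 2
        assert (labels == NOISE).mean() <= 0.01

    def test_uniform_scatter_all_noise(self, rng):
        emb = rng.uniform(0, 1, size=(100, 2))
        labels = cluster_embedding(emb, min_cluster_size=60, min_samples=60)
        assert (labels == NOISE).all()

    def test_duplication_preserves_partition(self, rng):
        emb = np.vstack(
            [rng.normal(0, 1, (150, 2)), rng.normal(15, 1, (150, 2))]
        )
        base = cluster_embedding(emb, 11, 11)
        doubled = cluster_embedding(np.vstack([emb, emb]), 22, 22)
        assert adjusted_rand(base, doubled[:300], ignore_noise=False) == pytest.approx(
            1.0
        )

    def test_nonfinite_embedding_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            cluster_embedding(np.array([[0.0, np.inf]]), 2)


class TestSilhouette:
    def test_separation_limit_approaches_one(self, rng):
        a = rng.normal(0, 0.1, (20, 2))
        for gap, lo in [(5, 0.9), (50, 0.99)]:
            X = np.vstack([a, a + gap])
            labels = np.repeat([0, 1], 20)
            assert evaluate_silhouette(X, labels) > lo

    def test_colocated_split_cluster_nonpositive(self, rng):
        X = np.tile(rng.normal(size=(3, 2)), (2, 1))
        labels = np.array([0, 0, 0, 1, 1, 1])  # same 3 points labeled twice
        assert evaluate_silhouette(X, labels) <= 0

    def test_hand_computed_four_point_example(self):
        """Two pairs at within-distance 1, between-distance ~10: the
        closed-form mean silhouette is ((9.5/10.5)+(8.5/9.5))/2."""
        X = np.array([[0.0, 0], [1, 0], [10, 0], [11, 0]])
        labels = np.array([0, 0, 1, 1])
        expected = ((10.5 - 1) / 10.5 + (9.5 - 1) / 9.5) / 2
        assert evaluate_silhouette(X, labels) == pytest.approx(expected)

    def test_single_cluster_undefined(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            evaluate_silhouette(rng.normal(size=(10, 2)), np.zeros(10))


class TestLabelPhenotypes:
    def make_summaries(self, rows):
        return pd.DataFrame(
            rows, columns=["bai_mean", "phq9_mean", "pclc_mean"]
        )

    def test_published_cluster_means_map_to_names(self):
        s = self.make_summaries(
            [[7.76, 5.09, 37.14], [5.03, 2.34, 20.81], [1.15, 1.08, 21.52], [0.0, 0.05, 17.1]]
        )
        names = label_phenotypes(s)
        assert names == {
            0: "ptsd",
            1: "anxiety",
            2: "mixed_anxiety_depression",
            3: "minimal_symptom",
        }

    def test_floor_cluster_is_minimal(self):
        s = self.make_summaries([[0, 0, 17], [10, 10, 40], [4, 2, 21], [1, 1, 22]])
        assert label_phenotypes(s)[0] == "minimal_symptom"

    def test_subthreshold_pair_split_by_bai(self):
        s = self.make_summaries([[5.03, 2, 21], [1.15, 2, 21], [0, 0, 17]])
        names = label_phenotypes(s)
        assert names[0] == "anxiety"
        assert names[1] == "mixed_anxiety_depression"

    def test_no_qualifying_ptsd_leaves_unlabeled_never_dropped(self):
        s = self.make_summaries([[1, 1, 20], [2, 2, 21], [3, 3, 22], [0, 0, 17], [4, 4, 23]])
        names = label_phenotypes(s)
        assert set(names) == set(s.index)
        assert "ptsd" not in names.values()
        assert "unlabeled" in names.values()


class TestPhenotypeClusterModel:
    @pytest.fixture(scope="class")
    def fit(self, scored_cohort):
        return PhenotypeCluster(scored_cohort, seed=77).fit()

    def test_partition_property(self, fit, scored_cohort):
        sizes = sum(fit.cluster_sizes.values()) + fit.n_noise
        assert sizes == len(scored_cohort)
        assert len(fit.labels) == len(scored_cohort)

    def test_silhouette_in_range(self, fit):
        assert -1 <= fit.silhouette <= 1

    def test_assignments_table_shape(self, fit, scored_cohort):
        a = fit.assignments()
        assert {"cluster", "phenotype", "umap1", "umap2"} <= set(a.columns)
        assert len(a) == len(scored_cohort)

    def test_weighted_mean_conservation_without_noise(self, scored_cohort):
        """With noise reassigned, the size-weighted cluster means equal the
        cohort means of the totals exactly."""
        res = PhenotypeCluster(scored_cohort, seed=77, reassign_noise=True).fit()
        assert res.n_noise == 0
        s = res.summaries
        for col, total in [
            ("bai_mean", "bai_total"),
            ("phq9_mean", "phq9_total"),
            ("pclc_mean", "pclc_total"),
        ]:
            weighted = (s[col] * s["n"]).sum() / s["n"].sum()
            assert weighted == pytest.approx(scored_cohort[total].mean())

    def test_summary_renders(self, fit):
        text = fit.summary()
        assert "silhouette" in text and "clusters" in text

    def test_latent_labels_recovered_better_than_chance(self, fit, scored_cohort):
        assert fit.ari(scored_cohort["latent_phenotype"]) > 0.3
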