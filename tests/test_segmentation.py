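"""Dimension reduction, constrained OPTICS, comparators, ridge evaluation."""

import numpy as np
import pandas as pd
import pytest

from hicost import (
    comparator_clusterings,
    evaluate_solutions,
    optics_cluster,
    pca_reduce,
    propagate_labels,
    tsne_embed,
)
from hicost.features import DedupResult, FeatureMatrix
from hicost.segmentation import ConstraintError, EmbeddingResult, _pam_kmedoids


def _df(x: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(x, index=[f"p{i}" for i in range(len(x))])


class TestPCA:
    def test_iid_columns_need_ceil_fraction(self):
        # ~equal eigenvalues: reaching 80% of variance takes 8 of 10 columns
        rng = np.random.default_rng(0)
        x = _df((rng.random((5000, 10)) < 0.5).astype(float))
        emb = pca_reduce(x, 0.80)
        assert emb.n_components == 8

    def test_low_rank_matrix(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(2, 6))
        coeff = rng.normal(size=(200, 2))
        emb = pca_reduce(_df(coeff @ basis), 0.80)
        assert emb.n_components <= 2

    def test_variance_target_met_minimally(self):
        # oracle: full eigendecomposition of the standardized covariance
        rng = np.random.default_rng(2)
        x = rng.normal(size=(300, 12)) @ rng.normal(size=(12, 12))
        xs = (x - x.mean(0)) / x.std(0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(xs.T)))[::-1]
        cum = np.cumsum(eig) / eig.sum()
        k_expected = int(np.searchsorted(cum, 0.80 - 1e-12) + 1)
        emb = pca_reduce(_df(x), 0.80)
        assert emb.n_components == k_expected
        assert emb.cumulative_variance >= 0.80

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            pca_reduce(_df(np.eye(5)), 1.5)


def _blob_embedding(n_blobs=6, per_blob=80, seed=0, spread=0.5):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-50, 50, size=(n_blobs, 2))
    coords = np.vstack(
        [c + rng.normal(scale=spread, size=(per_blob, 2)) for c in centers]
    )
    truth = np.repeat(np.arange(n_blobs), per_blob)
    return EmbeddingResult(scores=coords, n_components=2,
                           cumulative_variance=1.0, coords=coords), truth


class TestTSNE:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        scores = np.vstack([rng.normal(loc=c, size=(60, 5)) for c in (0, 8)])
        emb = EmbeddingResult(scores=scores, n_components=5, cumulative_variance=1.0)
        a = tsne_embed(emb, perplexity=15, seed=4)
        b = tsne_embed(emb, perplexity=15, seed=4)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_blobs_stay_separated(self):
        rng = np.random.default_rng(5)
        scores = np.vstack([rng.normal(loc=c, scale=0.3, size=(80, 5)) for c in (0, 10)])
        emb = tsne_embed(
            EmbeddingResult(scores=scores, n_components=5, cumulative_variance=1.0),
            perplexity=20, seed=6,
        )
        a, b = emb.coords[:80], emb.coords[80:]
        centroid_gap = np.linalg.norm(a.mean(0) - b.mean(0))
        within = np.percentile(np.linalg.norm(a - a.mean(0), axis=1), 95)
        assert centroid_gap > within

    def test_perplexity_bound(self):
        emb = EmbeddingResult(scores=np.zeros((50, 3)), n_components=3,
                              cumulative_variance=1.0)
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(emb, perplexity=30)


class TestOptics:
    def test_recovers_planted_blobs(self):
        emb, truth = _blob_embedding()
        sol = optics_cluster(emb, min_clusters=5, min_share=0.01)
        assert sol.constraints_ok
        from sklearn.metrics import adjusted_rand_score

        mask = sol.labels != -1
        assert adjusted_rand_score(truth[mask], sol.labels[mask]) >= 0.8

    def test_four_cluster_solution_marked_noncompliant(self):
        from hicost.segmentation import _solution_from_labels

        labels = np.repeat([0, 1, 2, 3], 50)
        sol = _solution_from_labels(
            labels, "optics", {}, np.ones(200, dtype=int), min_clusters=5, min_share=0.01
        )
        assert not sol.constraints_ok
        assert "4 clusters" in sol.constraint_notes

    def test_small_share_cluster_marked_noncompliant(self):
        from hicost.segmentation import _solution_from_labels

        labels = np.array([0] * 990 + [1] * 5 + [2] * 5)
        sol = _solution_from_labels(
            labels, "optics", {}, np.ones(1000, dtype=int), min_clusters=1, min_share=0.01
        )
        assert not sol.constraints_ok
        assert "below 1%" in sol.constraint_notes

    def test_uniform_noise_raises_structured_failure(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(-1, 1, size=(400, 2))
        emb = EmbeddingResult(scores=coords, n_components=2,
                              cumulative_variance=1.0, coords=coords)
        with pytest.raises(ConstraintError, match="nearest misses"):
            optics_cluster(emb, min_clusters=10, min_share=0.10)

    def test_share_constraint_uses_expanded_multiplicities(self):
        # 5 tight blobs of 30 unique rows; one blob's rows carry weight 10
        emb, truth = _blob_embedding(n_blobs=5, per_blob=30, seed=9, spread=0.2)
        mult = np.ones(150, dtype=int)
        mult[truth == 0] = 10
        unique = pd.DataFrame(
            np.zeros((150, 2)), index=[f"u{i}" for i in range(150)]
        )
        dd = DedupResult(
            unique=unique,
            representative=pd.Series([f"u{i}" for i in range(150)],
                                     index=[f"p{i}" for i in range(150)]),
            multiplicity=pd.Series(mult, index=unique.index),
        )
        sol = optics_cluster(emb, dedup=dd, min_clusters=5, min_share=0.01)
        total = mult.sum()
        for c, size in sol.cluster_sizes.items():
            assert size / total >= 0.01

    def test_constraint_monotone_in_min_share(self):
        emb, _ = _blob_embedding(n_blobs=6, per_blob=50, seed=10)
        counts = []
        for share in (0.01, 0.05, 0.10, 0.20):
            try:
                _, cands = optics_cluster(
                    emb, min_clusters=5, min_share=share, return_all=True
                )
                counts.append(sum(c.constraints_ok for c in cands))
            except ConstraintError:
                counts.append(0)
        assert counts == sorted(counts, reverse=True)


class TestComparators:
    def test_k1_single_cluster_noncompliant(self):
        emb, _ = _blob_embedding(n_blobs=2, per_blob=50)
        sols = comparator_clusterings(emb, k_range=(1,), min_clusters=5)
        assert all(s.n_clusters == 1 and not s.constraints_ok for s in sols)

    def test_kmedoids_reproducible(self):
        emb, _ = _blob_embedding()
        a = _pam_kmedoids(emb.coords, 6, seed=3)
        b = _pam_kmedoids(emb.coords, 6, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_comparators_competitive_on_blobs(self):
        from sklearn.metrics import adjusted_rand_score

        emb, truth = _blob_embedding(seed=11)
        optics_sol = optics_cluster(emb, min_clusters=5, min_share=0.01)
        mask = optics_sol.labels != -1
        optics_ari = adjusted_rand_score(truth[mask], optics_sol.labels[mask])
        comps = comparator_clusterings(emb, k_range=(6,))
        best_comp = max(
            adjusted_rand_score(truth, s.labels) for s in comps
        )
        assert best_comp >= optics_ari - 0.15

    def test_k_above_n_skipped(self):
        emb, _ = _blob_embedding(n_blobs=2, per_blob=10)
        sols = comparator_clusterings(emb, k_range=(5, 100))
        assert {s.params.get("k") for s in sols} == {5}


class TestEvaluate:
    def _clinical_and_solution(self, informative: bool, seed=0):
        rng = np.random.default_rng(seed)
        n, k = 300, 3
        labels = np.repeat(np.arange(k), n // k)
        x = (rng.random((n, 6)) < 0.1).astype(float)
        if informative:
            for c in range(k):
                x[labels == c, c] = 1.0
        clinical = pd.DataFrame(x, columns=[f"v{i}" for i in range(6)])
        from hicost.segmentation import _solution_from_labels

        sol = _solution_from_labels(
            labels, "test", {}, np.ones(n, dtype=int), 1, 0.0
        )
        return clinical, sol, rng

    def test_planted_structure_near_perfect(self):
        clinical, sol, _ = self._clinical_and_solution(informative=True)
        table = evaluate_solutions([sol], clinical, seed=1)
        assert table["mean_auc"].iloc[0] >= 0.9

    def test_random_labels_near_chance(self):
        clinical, sol, rng = self._clinical_and_solution(informative=False, seed=2)
        table = evaluate_solutions([sol], clinical, seed=1)
        assert table["mean_auc"].iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_column_order_invariant(self):
        clinical, sol, _ = self._clinical_and_solution(informative=True)
        a = evaluate_solutions([sol], clinical, seed=1)["mean_auc"].iloc[0]
        b = evaluate_solutions([sol], clinical[clinical.columns[::-1]], seed=1)["mean_auc"].iloc[0]
        assert a == pytest.approx(b, abs=1e-6)


class TestPropagate:
    def test_duplicates_share_label_and_sizes_add_up(self):
        unique = pd.DataFrame({"a": [1, 0]}, index=["u0", "u1"])
        rep = pd.Series(["u0", "u0", "u1"], index=["p1", "p2", "p3"])
        mult = pd.Series([2, 1], index=["u0", "u1"])
        dd = DedupResult(unique=unique, representative=rep, multiplicity=mult)
        from hicost.segmentation import _solution_from_labels

        sol = _solution_from_labels(
            np.array([3, -1]), "test", {}, mult.to_numpy(), 1, 0.0
        )
        labels = propagate_labels(sol, dd)
        assert labels.loc["p1"] == 3 and labels.loc["p2"] == 3
        assert labels.loc["p3"] == -1
        # expanded noise share matches a direct count
        assert (labels == -1).mean() == pytest.approx(sol.noise_share)
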