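"""Neuron-beta, SNN similarity, consensus co-clustering, arbor typing."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from axonmap.cluster import (
    cluster_arbors_kmeans,
    cluster_projection_et,
    cocluster,
    cut_and_prune,
    embed_2d,
    neuron_beta,
    pca_reduce,
    ranked_knn,
    snn_matrix,
    snn_similarity,
)
from axonmap.projection import strength_cell
from axonmap.synthetic import (
    FeatureSetSpec,
    PopulationSpec,
    make_feature_sets,
    make_population,
)

DISJOINT_ARCHETYPES = {
    "A": {30: 8.0, 40: 5.0},
    "B": {50: 9.0, 60: 4.0},
    "C": {70: 7.0, 80: 6.0},
}


class TestNeuronBeta:
    def test_identical_vectors_give_one(self):
        M = np.array([0.0, 1.0, 3.0, 2.0])
        assert neuron_beta(M, M) == pytest.approx(1.0)

    def test_affine_transform_gives_slope(self):
        M = np.array([0.0, 1.0, 3.0, 2.0, 5.0])
        assert neuron_beta(M, 2.0 * M + 7.0) == pytest.approx(2.0)

    def test_equals_ols_slope(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            M = rng.normal(size=12)
            S = rng.normal(size=12)
            slope = np.polyfit(M, S, 1)[0]
            assert neuron_beta(M, S) == pytest.approx(slope, abs=1e-12)

    def test_constant_mesoscale_rejected(self):
        with pytest.raises(ValueError, match="Var"):
            neuron_beta(np.ones(5), np.arange(5.0))


class TestPCAReduce:
    def test_rank_one_data_single_pc(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=10)
        X = np.outer(rng.normal(size=30), base)
        assert pca_reduce(X, 0.9).shape[1] == 1

    def test_isotropic_gaussian_needs_all_axes(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5000, 3))
        assert pca_reduce(X, 0.9).shape[1] == 3

    def test_reconstruction_error_is_discarded_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 6)) * [5, 3, 2, 1, 0.5, 0.1]
        Xc = X - X.mean(axis=0)
        from sklearn.decomposition import PCA

        pca = PCA().fit(Xc)
        scores = pca_reduce(X, 0.9)
        k = scores.shape[1]
        recon = scores @ pca.components_[:k]
        err = np.sum((Xc - recon) ** 2) / (len(X) - 1)
        assert err == pytest.approx(pca.explained_variance_[k:].sum(), rel=1e-9)


class TestEmbed2D:
    def test_blobs_stay_separated(self):
        rng = np.random.default_rng(4)
        X = np.vstack(
            [rng.normal(size=(30, 5)), rng.normal(size=(30, 5)) + 10.0]
        )
        labels = np.repeat([0, 1], 30)
        emb = embed_2d(X, seed=0)
        assert silhouette_score(emb, labels) > 0.5

    def test_same_seed_identical(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        np.testing.assert_array_equal(embed_2d(X, seed=3), embed_2d(X, seed=3))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            embed_2d(np.zeros((10, 3)), n_neighbors=15)


class TestSNN:
    def test_disjoint_neighbourhoods_zero(self):
        assert snn_similarity([1, 2, 3], [4, 5, 6], k=3) == 0.0

    def test_shared_top_neighbour(self):
        # v at rank 1 in both lists, k=10 -> 10 - (1+1)/2 = 9
        ni = [7] + list(range(20, 29))
        nj = [7] + list(range(40, 49))
        assert snn_similarity(ni, nj, k=10) == 9.0

    def test_shared_last_rank_is_zero_and_bounded(self):
        for k in range(1, 7):
            ni = list(range(10, 10 + k - 1)) + [99]
            nj = list(range(30, 30 + k - 1)) + [99]
            assert snn_similarity(ni, nj, k=k) == 0.0

    def test_enumerated_rank_configurations_match_formula(self):
        # every placement of two common neighbours in two rank lists
        from itertools import count

        k = 4
        fill_i = count(100)
        fill_j = count(100000)
        for ri in combinations(range(k), 2):
            for rj in permutations(range(k), 2):
                ni = [next(fill_i) for _ in range(k)]
                nj = [next(fill_j) for _ in range(k)]
                ni[ri[0]], ni[ri[1]] = 0, 1
                nj[rj[0]], nj[rj[1]] = 0, 1
                expected = max(
                    k - 0.5 * ((ri[0] + 1) + (rj[0] + 1)),
                    k - 0.5 * ((ri[1] + 1) + (rj[1] + 1)),
                )
                assert snn_similarity(ni, nj, k=k) == expected

    def test_symmetric(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 3))
        nn = ranked_knn(X, 5)
        for i in range(15):
            for j in range(15):
                assert snn_similarity(nn[i], nn[j], 5) == snn_similarity(
                    nn[j], nn[i], 5
                )

    def test_printed_variant_is_asymmetric(self):
        ni = [0] + [10, 11]
        nj = [12, 13] + [0]
        k = 3
        assert snn_similarity(ni, nj, k, as_printed=True) == pytest.approx(
            k - 0.5 * (1 + 0.5 * 3)
        )

    def test_matrix_matches_pairwise_formula(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 4))
        k = 6
        nn = ranked_knn(X, k)
        S = snn_matrix(X, k)
        for i in range(20):
            for j in range(20):
                if i != j:
                    assert S[i, j] == pytest.approx(
                        snn_similarity(nn[i], nn[j], k)
                    )


class TestCocluster:
    def test_consensus_block_structure_on_blobs(self):
        sets, labels = make_feature_sets(
            FeatureSetSpec(seed=0, n_clusters=2, cells_per_cluster=20)
        )
        res = cocluster(sets, iters=150, seed=0)
        C = res.consensus
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        assert C.min() >= 0.0 and C.max() <= 1.0
        off_block = C[np.ix_(labels == 0, labels == 1)]
        assert off_block.mean() < 0.05
        res = cut_and_prune(res)
        assigned = res.labels >= 0
        assert adjusted_rand_score(labels[assigned], res.labels[assigned]) == 1.0

    def test_invalid_parameters_rejected(self):
        sets, _ = make_feature_sets(FeatureSetSpec(seed=1))
        with pytest.raises(ValueError):
            cocluster(sets, iters=0)
        with pytest.raises(ValueError):
            cocluster(sets, sample_frac=1.5)

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError, match="share"):
            cocluster([np.zeros((10, 2)), np.zeros((11, 2))])

    def test_consensus_stable_in_iterations(self):
        sets, _ = make_feature_sets(FeatureSetSpec(seed=2))
        c_a = cocluster(sets, iters=150, seed=10).consensus
        c_b = cocluster(sets, iters=300, seed=11).consensus
        assert np.linalg.norm(c_a - c_b) / len(c_a) < 0.05


class TestCutAndPrune:
    def test_clean_data_zero_outliers_one_iteration(self):
        sets, labels = make_feature_sets(
            FeatureSetSpec(seed=3, separation=12.0)
        )
        res = cut_and_prune(cocluster(sets, iters=150, seed=0))
        assert res.outliers == []
        assert res.iterations == 1
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_planted_far_outlier_excluded(self):
        sets, labels = make_feature_sets(
            FeatureSetSpec(seed=4, n_clusters=2, n_outliers=1)
        )
        res = cut_and_prune(cocluster(sets, iters=150, seed=0))
        planted = np.flatnonzero(labels < 0)
        assert all(res.labels[p] == -1 for p in planted)

    def test_fixed_point_within_n_iterations(self):
        sets, labels = make_feature_sets(FeatureSetSpec(seed=5))
        res = cut_and_prune(cocluster(sets, iters=100, seed=0))
        assert res.iterations <= len(labels)


class TestClusterProjectionET:
    def test_planted_archetypes_recovered(self):
        for seed in range(3):
            cells, labels, _ = make_population(
                PopulationSpec(
                    seed=seed, archetypes=DISJOINT_ARCHETYPES, dropout=0.0
                )
            )
            pred = cluster_projection_et(
                strength_cell(cells.to_numpy()), seed=seed
            )
            assert len(set(pred)) == 3
            assert adjusted_rand_score(labels, pred) == 1.0

    def test_identical_cells_one_cluster(self):
        X = np.tile([[1.0, 2.0, 0.0]], (40, 1))
        pred = cluster_projection_et(X, seed=0, distance_threshold=1e-6)
        assert len(set(pred)) == 1

    def test_permutation_consistency(self):
        cells, labels, _ = make_population(
            PopulationSpec(seed=1, archetypes=DISJOINT_ARCHETYPES, dropout=0.0)
        )
        X = strength_cell(cells.to_numpy())
        perm = np.random.default_rng(0).permutation(len(X))
        a = cluster_projection_et(X, seed=0)
        b = cluster_projection_et(X[perm], seed=0)
        assert adjusted_rand_score(a[perm], b) == 1.0


class TestClusterArborsKmeans:
    def _arbor_features(self, seed, ratio=3.0, n=40):
        rng = np.random.default_rng(seed)
        half = n // 2
        radius = np.concatenate(
            [
                50.0 * rng.lognormal(0, 0.15, half),
                50.0 * ratio * rng.lognormal(0, 0.15, half),
            ]
        )
        feats = pd.DataFrame(
            {
                "area_2d": radius**2 * np.pi * rng.lognormal(0, 0.1, n),
                "total_length": radius * 30 * rng.lognormal(0, 0.1, n),
                "radius": radius,
                "depth_mean": rng.uniform(200, 400, n),
                "depth_std": rng.uniform(20, 60, n),
            }
        )
        labels = np.repeat([1, 2], half)
        return feats, labels

    @pytest.mark.parametrize("seed", range(3))
    def test_two_size_populations_recovered(self, seed):
        feats, labels = self._arbor_features(seed)
        pred = cluster_arbors_kmeans(feats, k=2, seed=seed)
        assert adjusted_rand_score(labels, pred) >= 0.95

    def test_type_one_is_smaller_radius(self):
        feats, _ = self._arbor_features(0)
        pred = cluster_arbors_kmeans(feats, k=2, seed=0)
        assert feats.loc[pred == 1, "radius"].mean() < feats.loc[
            pred == 2, "radius"
        ].mean()

    def test_k_one_single_label(self):
        feats, _ = self._arbor_features(1)
        assert set(cluster_arbors_kmeans(feats, k=1)) == {1}
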