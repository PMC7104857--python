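"""Standardization, PCA, permutation PC selection, PAM, SNN-Louvain."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from celltraction import (
    default_cohort,
    knn_graph,
    louvain_cluster,
    pam_cluster,
    pc1_trajectory,
    run_pca,
    significant_pcs,
    simulate_force_profile_cohort,
    snn_refine,
    standardize,
)


def _blobs(n_per=20, sep=10.0, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.zeros((3, dim))
    centers[1, 0] = sep
    centers[2, 1] = sep
    pts = np.vstack([rng.normal(c, 1.0, (n_per, dim)) for c in centers])
    labels = np.repeat([0, 1, 2], n_per)
    return pts, labels


class TestStandardize:
    def test_hand_z_score(self):
        pm = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 2.0, 4.0]}))
        assert np.allclose(pm.values[:, 0], [-1, 0, 1])
        assert np.allclose(pm.values.mean(axis=0), 0)
        assert np.allclose(pm.values.std(axis=0, ddof=1), 1)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 5))
        z1 = standardize(pd.DataFrame(x)).values
        z2 = standardize(pd.DataFrame(z1)).values
        assert np.allclose(z1, z2)

    def test_constant_feature_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(df)


class TestPCA:
    def test_collinear_points_give_single_component(self):
        t = np.linspace(0, 1, 20)
        df = pd.DataFrame({"x": t, "y": 2 * t + 0.5})
        pca = run_pca(standardize(df))
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_cloud_flat_spectrum(self):
        rng = np.random.default_rng(3)
        pca = run_pca(standardize(pd.DataFrame(rng.normal(size=(500, 5)))))
        assert np.all(np.abs(pca.explained_variance_ratio - 0.2) < 0.05)

    def test_reconstruction_and_ordering(self):
        rng = np.random.default_rng(4)
        pm = standardize(pd.DataFrame(rng.normal(size=(40, 6))))
        pca = run_pca(pm)
        centred = pm.values - pm.values.mean(axis=0)
        assert np.allclose(pca.scores @ pca.loadings.T, centred, atol=1e-10)
        evr = pca.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9


class TestSignificantPCs:
    def test_planted_two_factor_structure(self):
        rng = np.random.default_rng(4)
        n = 200
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        x = np.hstack(
            [
                np.outer(f1, rng.uniform(0.8, 1.2, 5)),
                np.outer(f2, rng.uniform(0.8, 1.2, 5)),
                rng.normal(size=(n, 20)),
            ]
        )
        x[:, :10] += rng.normal(0, 0.3, (n, 10))
        assert significant_pcs(standardize(pd.DataFrame(x)), 100, 0.05, seed=5) == 2

    def test_null_matrix_mostly_zero(self):
        # level check: null runs return 0 significant PCs at ~alpha=0.05
        # (binomial tolerance: allow 3 exceedances in 20 runs)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            pm = standardize(pd.DataFrame(rng.normal(size=(60, 10))))
            hits += significant_pcs(pm, 100, 0.05, seed=seed) == 0
        assert hits >= 17

    def test_few_permutations_warns(self):
        rng = np.random.default_rng(0)
        pm = standardize(pd.DataFrame(rng.normal(size=(20, 4))))
        with pytest.warns(UserWarning, match="permutations"):
            significant_pcs(pm, n_permutations=10, seed=0)


class TestPAM:
    def test_separated_blobs_fully_recovered(self):
        pts, labels = _blobs(sep=10.0)
        assign = pam_cluster(pts, k=3)
        assert adjusted_rand_score(labels, assign.labels) == 1.0
        assert sorted(np.unique(assign.labels)) == [1, 2, 3]

    def test_single_cluster_medoid_minimizes_total_distance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 3))
        assign = pam_cluster(pts, k=1)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        assert assign.medoids[0] == np.argmin(d.sum(axis=1))  # brute-force 1-medoid

    def test_medoids_are_data_points_and_duplicates_share_cluster(self):
        pts = np.vstack([_blobs(sep=8.0)[0], _blobs(sep=8.0)[0][:5]])
        assign = pam_cluster(pts, k=3)
        assert all(0 <= m < len(pts) for m in assign.medoids)
        # duplicated points end in the same cluster as their originals
        assert np.array_equal(assign.labels[-5:], assign.labels[:5])

    def test_invalid_k(self):
        pts = _blobs()[0]
        with pytest.raises(ValueError):
            pam_cluster(pts, k=0)
        with pytest.raises(ValueError):
            pam_cluster(pts, k=len(pts))


class TestKnnSnn:
    def test_collinear_hand_case(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        g = knn_graph(pts, k=1)
        assert g.knn[0, 0] == 1 and g.knn[1, 0] == 0 and g.knn[2, 0] == 1

    def test_complete_graph_at_k_n_minus_1(self):
        pts = np.random.default_rng(0).normal(size=(8, 2))
        g = knn_graph(pts, k=7)
        for i in range(8):
            assert set(g.knn[i]) == set(range(8)) - {i}

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            knn_graph(np.zeros((5, 2)), k=5)

    def test_blob_edges_mostly_intra(self):
        pts, labels = _blobs(sep=10.0)
        g = knn_graph(pts, k=10)
        intra = sum(
            labels[i] == labels[j] for i in range(len(pts)) for j in g.knn[i]
        )
        assert intra / (len(pts) * 10) > 0.95

    def test_jaccard_weights(self):
        # identical neighbourhoods → weight 1; disjoint → no edge
        pts = np.array([[0.0], [0.1], [0.2], [50.0], [50.1], [50.2]])
        g = snn_refine(knn_graph(pts, k=2), prune_below=0.0)
        assert g.snn[0][1]["weight"] == 1.0
        assert not g.snn.has_edge(0, 3)

    def test_intra_blob_weights_exceed_inter(self):
        pts, labels = _blobs(sep=6.0, seed=3)
        g = snn_refine(knn_graph(pts, k=10))
        intra, inter = [], []
        for i, j, w in g.snn.edges(data="weight"):
            (intra if labels[i] == labels[j] else inter).append(w)
        assert np.mean(intra) > np.mean(inter)


class TestLouvain:
    def test_two_cliques_one_bridge(self):
        import networkx as nx

        g = nx.Graph()
        for base in (0, 10):
            for i in range(10):
                for j in range(i + 1, 10):
                    g.add_edge(base + i, base + j, weight=1.0)
        g.add_edge(0, 10, weight=1.0)
        from celltraction.clustering import NeighborGraph

        assign = louvain_cluster(NeighborGraph(knn=np.zeros((20, 1), int), k=1, snn=g))
        assert len(np.unique(assign.labels)) == 2

    def test_empty_graph_rejected(self):
        import networkx as nx

        with pytest.raises(ValueError):
            louvain_cluster(nx.Graph())

    def test_full_path_recovers_planted_blobs(self):
        pts, labels = _blobs(sep=8.0, seed=5)
        assign = louvain_cluster(snn_refine(knn_graph(pts, k=15)), seed=0)
        assert adjusted_rand_score(labels, assign.labels) >= 0.9

    def test_modularity_beats_singletons(self):
        import networkx as nx

        pts, _ = _blobs(sep=6.0, seed=6)
        g = snn_refine(knn_graph(pts, k=10)).snn
        assign = louvain_cluster(snn_refine(knn_graph(pts, k=10)), seed=0)
        comms = [set(np.flatnonzero(assign.labels == c)) for c in np.unique(assign.labels)]
        q = nx.community.modularity(g, comms, weight="weight")
        q0 = nx.community.modularity(g, [{i} for i in g.nodes], weight="weight")
        assert q >= q0


class TestEndToEndCohort:
    def test_both_routes_recover_planted_groups_across_seeds(self):
        for seed in range(10):
            df, labels = simulate_force_profile_cohort(default_cohort(seed=seed))
            pm = standardize(df)
            pca = run_pca(pm)
            nsig = max(significant_pcs(pm, 100, 0.05, seed=seed + 500), 1)
            pam = pam_cluster(pca.scores[:, :nsig], k=3)
            louv = louvain_cluster(
                snn_refine(knn_graph(pca.scores[:, :nsig], k=20)), seed=seed
            )
            assert adjusted_rand_score(labels, pam.labels) >= 0.9
            assert adjusted_rand_score(labels, louv.labels) >= 0.9


class TestPc1Trajectory:
    def test_contractility_dominated_cohort_orders_by_force(self):
        rng = np.random.default_rng(9)
        n = 60
        force = rng.uniform(50, 600, n)
        feats = np.outer(force, np.full(8, 1.0)) + rng.normal(0, 10, (n, 8))
        df = pd.DataFrame(feats)
        pm = standardize(df)
        pca = run_pca(pm)
        assign = pam_cluster(pca.scores[:, :2], k=3)
        stats = pd.DataFrame({"mean_traction": force, "max_traction": force * 3})
        table, rho = pc1_trajectory(pca, assign, stats)
        assert abs(rho) >= 0.9
        assert table["pc1"].is_monotonic_increasing

    def test_null_features_uncorrelated(self):
        rng = np.random.default_rng(10)
        n = 80
        df = pd.DataFrame(rng.normal(size=(n, 6)))
        pm = standardize(df)
        pca = run_pca(pm)
        assign = pam_cluster(pca.scores[:, :2], k=3)
        stats = pd.DataFrame(
            {"mean_traction": rng.uniform(0, 1, n), "max_traction": rng.uniform(0, 1, n)}
        )
        _, rho = pc1_trajectory(pca, assign, stats)
        assert abs(rho) < 0.35
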