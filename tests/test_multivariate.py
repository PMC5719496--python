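import numpy as np
import pandas as pd
import pytest

from lipidims import (PeakList, build_intensity_matrix, cut_dendrogram,
                      hierarchical_cluster, pca, tic_normalize, zscore_rows)


class TestZScoreRows:
    def test_closed_form_row(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(zscore_rows(mat).to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_policy(self):
        mat = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_rows(mat)
        assert z.iloc[0].tolist() == [0.0, 0.0, 0.0]

    def test_random_matrix_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.uniform(0, 10, (20, 4)))
        z = zscore_rows(mat).to_numpy()
        # direct recomputation oracle
        assert np.abs(z.mean(axis=1)).max() < 1e-9
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-9

    def test_idempotent_on_nondegenerate_rows(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(5, 6)))
        once = zscore_rows(mat)
        twice = zscore_rows(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-9)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError, match="2 columns"):
            zscore_rows(pd.DataFrame([[1.0]]))


def naive_agglomerate(X, linkage):
    """O(n^3) oracle: recompute inter-cluster distances from raw points."""
    X = np.asarray(X, float)
    n = len(X)
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    clusters = {i: [i] for i in range(n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                ds = [D[i, j] for i in clusters[a] for j in clusters[b]]
                d = {"single": min, "complete": max,
                     "average": lambda v: sum(v) / len(v)}[linkage](ds)
                if best is None or (d, a, b) < best:
                    best = (d, a, b)
        d, a, b = best
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, d))
        nxt += 1
    return merges


class TestHierarchicalCluster:
    def test_nearest_pair_merges_first(self):
        dendro = hierarchical_cluster(np.array([[0.0], [1.0], [10.0]]))
        a, b, h = dendro.merges[0]
        assert {a, b} == {0, 1} and h == pytest.approx(1.0)

    def test_identical_rows_merge_at_height_zero(self):
        dendro = hierarchical_cluster(np.ones((4, 3)))
        assert np.allclose(dendro.heights(), 0.0)

    @pytest.mark.parametrize("linkage", ["complete", "average", "single"])
    def test_merge_sequence_equals_naive_oracle(self, linkage):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(8, 5))
            dendro = hierarchical_cluster(X, linkage=linkage)
            oracle = naive_agglomerate(X, linkage)
            for (a, b, h), (oa, ob, oh) in zip(dendro.merges, oracle):
                assert (a, b) == (oa, ob)
                assert h == pytest.approx(oh)

    def test_complete_linkage_heights_nondecreasing(self):
        rng = np.random.default_rng(9)
        dendro = hierarchical_cluster(rng.normal(size=(12, 4)))
        h = dendro.heights()
        assert np.all(np.diff(h) >= -1e-12)
        assert len(dendro.merges) == 11

    def test_agrees_with_scipy_cophenetic_distances(self):
        from scipy.cluster.hierarchy import cophenet, linkage as scipy_linkage
        from scipy.spatial.distance import pdist
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        dendro = hierarchical_cluster(X, linkage="complete")
        Z = np.zeros((9, 4))
        sizes = {}
        for k, (a, b, h) in enumerate(dendro.merges):
            sizes[10 + k] = sizes.get(a, 1) + sizes.get(b, 1)
            Z[k] = [a, b, h, sizes[10 + k]]
        ours = cophenet(Z)
        ref = cophenet(scipy_linkage(pdist(X), method="complete"))
        np.testing.assert_allclose(np.sort(ours), np.sort(ref), rtol=1e-9)

    def test_row_permutation_invariant_heights(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(9, 3))
        perm = rng.permutation(9)
        h1 = hierarchical_cluster(X).heights()
        h2 = hierarchical_cluster(X[perm]).heights()
        np.testing.assert_allclose(h1, h2, atol=1e-9)

    def test_nonfinite_rejected(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="finite"):
            hierarchical_cluster(X)


class TestCutDendrogram:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(7)
        dendro = hierarchical_cluster(rng.normal(size=(6, 2)))
        assert len(set(cut_dendrogram(dendro, 6))) == 6
        assert set(cut_dendrogram(dendro, 1)) == {0}

    def test_forced_two_cluster_cut(self):
        dendro = hierarchical_cluster(np.array([[0.0], [1.0], [10.0]]))
        labels = cut_dendrogram(dendro, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_k_out_of_range(self):
        dendro = hierarchical_cluster(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            cut_dendrogram(dendro, 0)
        with pytest.raises(ValueError):
            cut_dendrogram(dendro, 4)


class TestPCA:
    def test_collinear_points_single_component(self):
        X = np.outer(np.arange(5, dtype=float), [1.0, 2.0])
        res = pca(X, scale=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 30))
        res = pca(X, scale=False)
        C = np.cov(X, rowvar=False, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        ours = (res.scores ** 2).sum(axis=0) / (X.shape[0] - 1)
        np.testing.assert_allclose(ours, evals[: len(ours)], rtol=1e-8)
        # loadings orthonormal
        G = res.loadings.T @ res.loadings
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)

    def test_matches_sklearn_up_to_sign(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(10)
        X = rng.normal(size=(15, 6))
        res = pca(X, n_components=3, scale=False)
        ref = sklearn.PCA(n_components=3).fit(X)
        np.testing.assert_allclose(np.abs(res.scores),
                                   np.abs(ref.transform(X)), atol=1e-8)
        np.testing.assert_allclose(res.explained_variance_ratio,
                                   ref.explained_variance_ratio_, rtol=1e-8)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(7, 4))
        res = pca(X, scale=False)
        recon = res.scores @ res.loadings.T + res.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_variance_fractions_nonincreasing(self):
        rng = np.random.default_rng(12)
        res = pca(rng.normal(size=(10, 5)))
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_components_beyond_rank_rejected(self):
        X = np.outer(np.arange(4, dtype=float), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="rank"):
            pca(X, n_components=3, scale=False)


class TestBuildIntensityMatrix:
    def test_aligns_ions_across_samples(self):
        def pl(mz, inten, sid):
            return tic_normalize(PeakList(np.asarray(mz, float),
                                          np.asarray(inten, float), sample_id=sid))
        mat = build_intensity_matrix(
            [pl([600.0, 650.0], [1, 3], "a"), pl([600.1, 650.05], [1, 1], "b"),
             pl([650.0], [2], "c")],
            cluster_tol=0.25, min_frequency=0.5)
        assert mat.shape == (2, 3)
        assert mat.loc[:, "c"].tolist() == [0.0, 1.0]
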