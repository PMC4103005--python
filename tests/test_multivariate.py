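"""Tests for z-scoring, Ward clustering, PCA, and the trait-group report."""

import numpy as np
import pandas as pd
import pytest
from oracles import brute_force_linkage

from myxphen.multivariate import (
    linkage_to_newick,
    pca,
    trait_group_report,
    ward_cluster,
    zscore,
)


class TestZScore:
    def test_sample_sd_convention(self):
        z = zscore(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z.values["a"], [-1.0, 0.0, 1.0])

    def test_constant_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = zscore(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0] * 3}))
        assert list(z.values.columns) == ["a"]

    def test_columns_standardized(self, rng):
        z = zscore(pd.DataFrame(rng.normal(3, 7, size=(40, 5))))
        np.testing.assert_allclose(z.values.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(ddof=1), 1.0, atol=1e-10)

    def test_roundtrip_inversion(self, rng):
        df = pd.DataFrame(rng.normal(10, 4, size=(20, 3)),
                          columns=list("abc"))
        z = zscore(df)
        np.testing.assert_allclose(z.invert().to_numpy(), df.to_numpy(),
                                   atol=1e-12)


class TestWardCluster:
    def test_separated_clouds_split_perfectly(self, rng):
        a = rng.normal(0, 1, size=(20, 4))
        b = rng.normal(10, 1, size=(20, 4))
        df = pd.DataFrame(np.vstack([a, b]),
                          index=[f"s{i}" for i in range(40)])
        cl = ward_cluster(df, k=2)
        labels = cl.labels.to_numpy()
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_merge_heights_monotone(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)))
        cl = ward_cluster(df, k=3)
        heights = cl.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            ward_cluster(pd.DataFrame(rng.normal(size=(4, 3))), k=5)

    def test_row_permutation_invariance(self, rng):
        from sklearn.metrics import adjusted_rand_score

        df = pd.DataFrame(rng.normal(size=(25, 4)),
                          index=[f"s{i}" for i in range(25)])
        cl1 = ward_cluster(df, k=3)
        perm = rng.permutation(25)
        cl2 = ward_cluster(df.iloc[perm], k=3)
        joined = pd.concat([cl1.labels.rename("a"), cl2.labels.rename("b")],
                           axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    @pytest.mark.parametrize("method,metric", [
        ("ward", "euclidean"), ("average", "euclidean"),
        ("average", "correlation"),
    ])
    def test_linkage_heights_match_brute_force_oracle(self, rng, method, metric):
        from myxphen.multivariate import hierarchical_cluster

        for n in (8, 14, 20):
            X = rng.normal(size=(n, 5))
            df = pd.DataFrame(X)
            cl = hierarchical_cluster(df, k=2, method=method, metric=metric)
            oracle = brute_force_linkage(X, method=method, metric=metric)
            np.testing.assert_allclose(
                np.sort(cl.linkage[:, 2]), np.sort(oracle[:, 2]), atol=1e-8)

    def test_newick_export_parses(self, rng):
        import io

        import skbio

        df = pd.DataFrame(rng.normal(size=(10, 3)),
                          index=[f"s{i}" for i in range(10)])
        cl = ward_cluster(df, k=2)
        tree = skbio.TreeNode.read(
            io.StringIO(linkage_to_newick(cl.linkage, list(df.index))))
        assert {t.name for t in tree.tips()} == set(df.index)


class TestPCA:
    def test_rank_one_data_pc1_is_everything(self):
        t = np.linspace(-1, 1, 30)
        df = pd.DataFrame(np.outer(t, [1.0, 2.0, -1.0]))
        res = pca(df)
        assert res.variance_explained[0] == pytest.approx(100.0, abs=1e-8)
        assert res.variance_explained.sum() == pytest.approx(100.0, abs=1e-8)

    def test_isotropic_data_near_uniform_variance(self, rng):
        df = pd.DataFrame(rng.normal(size=(4000, 8)))
        res = pca(zscore(df))
        assert np.abs(res.variance_explained - 12.5).max() < 3.0

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 6)))
        z = zscore(df)
        res = pca(z)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(6), atol=1e-8)
        recon = res.scores.to_numpy() @ L.T + z.values.to_numpy().mean(0)
        np.testing.assert_allclose(recon, z.values.to_numpy(), atol=1e-8)

    def test_scores_covariance_diagonal_matches_variance(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 5)))
        df.iloc[:, 1] += 2 * df.iloc[:, 0]
        res = pca(zscore(df))
        cov = np.cov(res.scores.to_numpy(), rowvar=False, ddof=1)
        np.testing.assert_allclose(cov, np.diag(np.diag(cov)), atol=1e-8)
        frac = np.diag(cov) / np.diag(cov).sum() * 100
        np.testing.assert_allclose(frac, res.variance_explained, atol=1e-8)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.decomposition import PCA as SKPCA

        df = pd.DataFrame(rng.normal(size=(80, 5)))
        res = pca(zscore(df))
        sk = SKPCA().fit(zscore(df).values.to_numpy())
        np.testing.assert_allclose(
            res.variance_explained, sk.explained_variance_ratio_ * 100,
            atol=1e-8)

    def test_two_factor_structure_captured(self, rng):
        n = 2000
        fa, fb = rng.normal(size=n), rng.normal(size=n)
        lam = np.sqrt(0.7)
        cols = {f"a{i}": lam * fa + np.sqrt(0.3) * rng.normal(size=n)
                for i in range(6)}
        cols |= {f"b{i}": lam * fb + np.sqrt(0.3) * rng.normal(size=n)
                 for i in range(2)}
        res = pca(zscore(pd.DataFrame(cols)))
        assert res.variance_explained[:2].sum() >= 70.0
        # loading signs group by factor on PC1 (the A-factor component)
        pc1 = res.loadings["PC1"]
        a_signs = np.sign(pc1[[f"a{i}" for i in range(6)]])
        assert len(set(a_signs)) == 1


class TestTraitGroupReport:
    def test_singleton_groups_at_k_equals_n(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)),
                          columns=list("abcde"))
        cl = ward_cluster(df, axis="traits", k=5)
        rep = trait_group_report(cl)
        assert len(rep["groups"]) == 5
        assert all(len(m) == 1 for m in rep["groups"].values())

    def test_correlated_trait_block_co_clusters(self):
        # traits simulated from the library's correlation sign pattern:
        # area/circularity/soft/hard form one group
        from myxphen.synthetic import SimulationConfig, simulate_trait_table

        cfg = SimulationConfig(n_strains=301, effect_fraction=1.0, rng_seed=13)
        table, _ = simulate_trait_table(cfg)
        z = zscore(table.summary_matrix(include_wildtype=False))
        cl = ward_cluster(z, axis="traits", k=2)
        labels = cl.labels
        block = {"area", "circularity", "soft", "hard"}
        assert len({labels[t] for t in block}) == 1
        assert labels["grayness"] != labels["area"]

    def test_uncorrelated_traits_flagged_unstable(self, rng):
        df = pd.DataFrame(rng.normal(size=(300, 8)),
                          columns=[f"t{i}" for i in range(8)])
        z = zscore(df)
        cl = ward_cluster(z, axis="traits", k=2)
        rep = trait_group_report(cl, z.values)
        assert rep["silhouette"] < 0.2
        assert rep["stable"] is False
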