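"""Co-expression network construction: adjacency, TOM, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest

from musclegrn import coexpression as cx
from musclegrn.io import ExpressionMatrix
from musclegrn.synthetic import SynthConfig, gen_module_expression


def _matrix(values, prefix="G"):
    # global constant shift onto a non-negative scale; correlations unchanged
    values = np.asarray(values, dtype=float)
    values = values - min(values.min(), 0.0) + 0.1
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(values.shape[0])],
                     columns=[f"S{j}" for j in range(values.shape[1])]),
        "log2fpkm1")


class TestSampleOutliers:
    @staticmethod
    def _tissue_panel(rng, n_genes, n_samples, outlier_cols=()):
        """Samples share a heterogeneous gene profile; outliers get a permuted one."""
        mu = rng.uniform(0, 12, size=n_genes)
        x = mu[:, None] + rng.standard_normal((n_genes, n_samples)) * 0.5
        for c in outlier_cols:
            x[:, c] = rng.permutation(mu) + rng.standard_normal(n_genes) * 0.5
        return np.clip(x, 0, None)

    def test_planted_outliers_excluded(self):
        rng = np.random.default_rng(3)
        vals = self._tissue_panel(rng, 300, 475, outlier_cols=(5, 200))
        m = _matrix(vals, prefix="G")
        kept, excluded = cx.detect_sample_outliers(m)
        assert sorted(excluded) == ["S200", "S5"]
        assert kept.shape[1] == 473

    def test_homogeneous_samples_kept(self):
        rng = np.random.default_rng(4)
        m = _matrix(self._tissue_panel(rng, 100, 30))
        kept, excluded = cx.detect_sample_outliers(m)
        assert excluded == []

    def test_single_extreme_sample_matches_zscore_recomputation(self):
        rng = np.random.default_rng(5)
        vals = self._tissue_panel(rng, 200, 20, outlier_cols=(7,))
        m = _matrix(vals)
        kept, excluded = cx.detect_sample_outliers(m)
        # brute-force recomputation of the connectivity z-scores
        c = np.corrcoef(m.values.to_numpy().T)
        conn = c.sum(axis=1) - 1
        z = (conn - conn.mean()) / conn.std()
        expected = [m.sample_ids[i] for i in np.flatnonzero(z < -2.5)]
        assert excluded == expected == ["S7"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            cx.detect_sample_outliers(_matrix(np.random.default_rng(0).random((5, 3))))


class TestSoftThreshold:
    def test_beta_is_smallest_qualifying_power(self):
        cfg = SynthConfig(seed=2, n_background=300, noise_sd=0.3)
        m, _ = gen_module_expression((60, 50), 80, 0.95, cfg)
        params = cx.CoexpressionParams(candidate_powers=range(1, 13))
        beta, table, reached = cx.pick_soft_threshold(m, params)
        # brute force over all candidate powers using the published rule
        qualifying = table.loc[(table.signed_r2 >= params.target_r2) &
                               (table.mean_connectivity >= params.min_mean_connectivity),
                               "power"]
        if reached:
            assert beta == int(qualifying.iloc[0])
        else:
            assert beta == int(table.loc[table.signed_r2.idxmax(), "power"])

    def test_pure_noise_flagged(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.standard_normal((60, 40)))
        beta, table, reached = cx.pick_soft_threshold(m)
        assert not reached
        # any high-R2 power on noise is an empty-network artifact
        usable = table.mean_connectivity >= 1.0
        assert (table.loc[usable, "signed_r2"] < 0.8).all()

    def test_duplicated_genes_keep_unit_connectivity(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((5, 30))
        vals = np.vstack([base, base])  # each gene has a perfect twin
        m = _matrix(vals)
        for p in (1, 6, 14):
            adj = cx.adjacency(m, p).to_numpy()
            assert (adj.sum(axis=1) >= 1 - 1e-9).all()

    def test_constant_gene_rejected(self):
        vals = np.random.default_rng(0).random((12, 10))
        vals[3] = 2.0
        with pytest.raises(ValueError, match="constant gene"):
            cx.pick_soft_threshold(_matrix(vals))


class TestAdjacency:
    @pytest.mark.parametrize("cor,beta,expected", [(-0.5, 1, 0.5), (0.5, 2, 0.25)])
    def test_hand_values(self, cor, beta, expected):
        # two genes engineered to have exactly the requested correlation
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = cor * x + np.sqrt(1 - cor ** 2) * np.array([1.0, 1.0, -1.0, -1.0])
        a = cx.adjacency(_matrix(np.vstack([x, y])), beta)
        assert a.iloc[0, 1] == pytest.approx(expected)
        assert a.iloc[0, 0] == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((10, 25))
        beta = 6
        a = cx.adjacency(_matrix(vals), beta).to_numpy()
        c = np.corrcoef(vals)
        expected = np.abs(c) ** beta
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(a, expected)
        assert np.allclose(a, a.T) and a.min() >= 0 and a.max() <= 1


class TestTom:
    def test_hand_example_path(self):
        a = pd.DataFrame([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        tom = cx.tom_similarity(a)
        assert tom.loc["a", "b"] == pytest.approx(0.5)

    def test_hand_example_triangle(self):
        a = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        tom = cx.tom_similarity(a)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_adjacency(self):
        a = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        tom = cx.tom_similarity(a).to_numpy()
        assert np.allclose(tom - np.eye(4), 0.0)

    def test_asymmetric_rejected(self):
        a = pd.DataFrame([[0, 0.2], [0.3, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="symmetric"):
            cx.tom_similarity(a)


class TestModules:
    def test_two_planted_blocks_recovered(self):
        cfg = SynthConfig(seed=6, n_background=0, noise_sd=0.3)
        m, labels = gen_module_expression((40, 40), 60, 0.9, cfg)
        tom = cx.tom_similarity(cx.adjacency(m, 6))
        detected, _ = cx.cluster_modules(tom)
        # same partition as planted, up to label permutation
        tab = pd.crosstab(labels, detected)
        assert (tab.max(axis=1) == tab.sum(axis=1)).all()
        assert detected.max() == 2

    def test_undersized_cluster_unassigned(self):
        cfg = SynthConfig(seed=6, n_background=40, noise_sd=0.3)
        m, _ = gen_module_expression((10,), 60, 0.9, cfg)
        tom = cx.tom_similarity(cx.adjacency(m, 6))
        detected, _ = cx.cluster_modules(tom)  # min_module_size 30 > 10
        assert (detected.iloc[:10] == 0).all()

    def test_identical_genes_single_module(self):
        base = np.random.default_rng(2).standard_normal(40)
        vals = np.tile(base, (35, 1))
        tom = pd.DataFrame(np.ones((35, 35)),
                           index=[f"G{i}" for i in range(35)],
                           columns=[f"G{i}" for i in range(35)])
        np.fill_diagonal(tom.values, 1.0)
        detected, _ = cx.cluster_modules(tom)
        assert (detected == 1).all()

    def test_too_few_genes_warns_all_unassigned(self):
        tom = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        with pytest.warns(UserWarning):
            detected, _ = cx.cluster_modules(tom)
        assert (detected == 0).all()


class TestEigengenes:
    def test_rank_one_module(self):
        base = np.random.default_rng(3).standard_normal(25)
        vals = np.vstack([2 * base + 1, 0.5 * base - 3, base])
        m = _matrix(vals)
        labels = pd.Series([1, 1, 1], index=m.gene_ids)
        eig, var = cx.module_eigengenes(m, labels)
        std = (vals[2] - vals[2].mean()) / vals[2].std()
        assert abs(np.corrcoef(eig.loc[1], std)[0, 1]) == pytest.approx(1.0)
        assert var.loc[1] == pytest.approx(1.0)

    def test_matches_direct_svd(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal((8, 30))
        m = _matrix(vals)
        labels = pd.Series(1, index=m.gene_ids)
        eig, var = cx.module_eigengenes(m, labels)
        sub = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
        _, s, vt = np.linalg.svd(sub, full_matrices=False)
        assert np.allclose(np.abs(eig.loc[1].to_numpy()), np.abs(vt[0]))
        assert var.loc[1] == pytest.approx(s[0] ** 2 / (s ** 2).sum())

    def test_sign_orientation(self):
        rng = np.random.default_rng(10)
        for seed in range(5):
            vals = np.random.default_rng(seed).standard_normal((6, 20))
            m = _matrix(vals)
            labels = pd.Series(1, index=m.gene_ids)
            eig, _ = cx.module_eigengenes(m, labels)
            sub = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
            assert np.corrcoef(eig.loc[1], sub.mean(axis=0))[0, 1] >= 0

    def test_unit_norm(self, cfg):
        m, labels = gen_module_expression((10, 8), 30, 0.9, cfg)
        eig, _ = cx.module_eigengenes(m, labels)
        assert np.allclose(np.linalg.norm(eig.to_numpy(), axis=1), 1.0)


class TestMerge:
    def _near_duplicate_modules(self, n_modules, seed=12):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal(50)
        blocks = [0.95 * f + 0.05 * rng.standard_normal((20, 50)) for _ in range(n_modules)]
        vals = np.vstack(blocks)
        m = _matrix(vals)
        labels = pd.Series(np.repeat(np.arange(1, n_modules + 1), 20), index=m.gene_ids)
        return m, labels

    def test_highly_correlated_modules_merged(self):
        m, labels = self._near_duplicate_modules(2)
        merged = cx.merge_modules(m, labels)
        assert merged.nunique() == 1

    def test_uncorrelated_modules_unchanged(self, cfg):
        m, labels = gen_module_expression((20, 20), 50, 0.9, cfg)
        merged = cx.merge_modules(m, labels)
        assert merged.nunique() == 2

    def test_postcondition_all_correlations_below_threshold(self):
        m, labels = self._near_duplicate_modules(3)
        merged = cx.merge_modules(m, labels)
        mods = sorted(merged.unique())
        if len(mods) > 1:
            eig, _ = cx.module_eigengenes(m, merged)
            c = np.corrcoef(eig.to_numpy())
            np.fill_diagonal(c, 0.0)
            assert c.max() <= 0.75 + 1e-9

    def test_idempotent(self, cfg):
        m, labels = gen_module_expression((20, 20, 15), 50, 0.9, cfg)
        once = cx.merge_modules(m, labels)
        twice = cx.merge_modules(m, once)
        assert (once == twice).all()
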