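"""Compositional statistics: CLR, PCA, Aitchison, PERMANOVA, ANOVA/Tukey."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phytoflux import stats

import _oracles as oracles


def _frame(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"f{j}" for j in range(arr.shape[1])])


class TestClr:
    def test_uniform_row_maps_to_zero(self):
        clr = stats.clr_transform(_frame([[1, 1, 1, 1]]), pseudocount=0)
        np.testing.assert_allclose(clr.to_numpy(), 0.0, atol=1e-12)

    def test_two_part_closed_form(self):
        clr = stats.clr_transform(_frame([[1, 4]]), pseudocount=0)
        np.testing.assert_allclose(clr.to_numpy()[0],
                                   [-np.log(2), np.log(2)], atol=1e-12)

    def test_zero_counts_without_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            stats.clr_transform(_frame([[0, 1]]), pseudocount=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_elementwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 40, size=(8, 12))
        clr = stats.clr_transform(_frame(x), pseudocount=1)
        np.testing.assert_allclose(clr.to_numpy(), oracles.clr_brute(x, 1),
                                   atol=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(3, 8).flatmap(
        lambda m: st.lists(st.lists(st.integers(0, 1000),
                                    min_size=m, max_size=m),
                           min_size=2, max_size=6)))
    def test_rows_always_sum_to_zero(self, rows):
        clr = stats.clr_transform(_frame(np.array(rows)), pseudocount=0.5)
        np.testing.assert_allclose(clr.sum(axis=1).to_numpy(), 0.0, atol=1e-8)


class TestAitchison:
    def test_identical_rows_have_zero_distance(self):
        clr = stats.clr_transform(_frame([[2, 3, 4], [2, 3, 4]]))
        d = stats.aitchison_distance(clr)
        assert d.iloc[0, 1] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_and_is_a_metric(self, seed):
        rng = np.random.default_rng(seed)
        clr = stats.clr_transform(_frame(rng.integers(0, 30, size=(7, 9))))
        d = stats.aitchison_distance(clr).to_numpy()
        np.testing.assert_allclose(d, oracles.aitchison_brute(clr), atol=1e-8)
        # symmetry, zero diagonal, triangle inequality
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_invariant_under_feature_reordering(self):
        rng = np.random.default_rng(0)
        x = _frame(rng.integers(0, 30, size=(6, 10)))
        perm = rng.permutation(x.columns)
        d1 = stats.aitchison_distance(stats.clr_transform(x))
        d2 = stats.aitchison_distance(stats.clr_transform(x[perm]))
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-10)


class TestPca:
    def test_two_samples_give_single_component(self):
        res = stats.pca_svd(_frame([[0.0, 1.0, 2.0], [2.0, 0.0, 1.0]]))
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        x = _frame(rng.normal(size=(12, 7)))
        res = stats.pca_svd(x)
        centered = x.to_numpy() - x.to_numpy().mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - centered).max() < 1e-8

    def test_variance_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        x = _frame(rng.normal(size=(15, 6)))
        res = stats.pca_svd(x)
        c = np.cov(x.to_numpy(), rowvar=False, ddof=0)
        evals = np.sort(np.linalg.eigvalsh(c))[::-1]
        np.testing.assert_allclose(res.variance_explained,
                                   evals / evals.sum(), atol=1e-9)

    def test_matches_sklearn_reference(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 5))
        res = stats.pca_svd(_frame(x))
        ref = sklearn_pca().fit(x)
        np.testing.assert_allclose(res.variance_explained,
                                   ref.explained_variance_ratio_, atol=1e-9)

    def test_rank_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            stats.pca_svd(_frame([[1.0, 1.0], [1.0, 1.0]]))

    def test_variance_fractions_sum_to_one_and_decrease(self):
        rng = np.random.default_rng(4)
        res = stats.pca_svd(_frame(rng.normal(size=(10, 8))))
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.variance_explained) <= 1e-12).all()


def _two_clouds(n=8, offset=50.0, seed=0):
    from scipy.spatial.distance import pdist, squareform
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, 4))
    b = rng.normal(size=(n, 4))
    b[:, 0] += offset
    d = squareform(pdist(np.vstack([a, b])))
    labels = ["g1"] * n + ["g2"] * n
    return pd.DataFrame(d), labels


class TestPermanova:
    def test_extreme_separation_reaches_minimal_p(self):
        dist, labels = _two_clouds(offset=100.0)
        res = stats.permanova(dist, labels, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_statistic_invariant_to_label_renaming(self):
        dist, labels = _two_clouds(offset=3.0)
        renamed = ["B" if l == "g1" else "A" for l in labels]
        r1 = stats.permanova(dist, labels, n_perm=99, seed=1)
        r2 = stats.permanova(dist, renamed, n_perm=99, seed=1)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, abs=1e-12)

    def test_fixed_seed_is_bit_reproducible(self):
        dist, labels = _two_clouds(offset=2.0)
        r1 = stats.permanova(dist, labels, n_perm=499, seed=7)
        r2 = stats.permanova(dist, labels, n_perm=499, seed=7)
        assert (r1.pseudo_F, r1.p_value) == (r2.pseudo_F, r2.p_value)

    def test_p_never_below_one_over_nperm_plus_one(self):
        dist, labels = _two_clouds(offset=100.0)
        res = stats.permanova(dist, labels, n_perm=99, seed=0)
        assert res.p_value >= 1.0 / 100.0

    def test_pseudo_f_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 5))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(x))
        labels = ["a"] * 6 + ["b"] * 3 + ["c"] * 3
        ours = stats.permanova(pd.DataFrame(d), labels, n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(d)
        theirs = skbio_stats.permanova(dm, grouping=labels, permutations=99)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_singleton_group_rejected(self):
        dist, labels = _two_clouds()
        labels = list(labels)
        labels[0] = "lonely"
        with pytest.raises(ValueError, match="fewer than 2"):
            stats.permanova(dist, labels, n_perm=9)


class TestPairwisePermanova:
    def test_two_groups_adjusted_equals_raw(self):
        dist, labels = _two_clouds(offset=4.0)
        (res,) = stats.pairwise_permanova(dist, labels, n_perm=99, seed=0)
        assert res.adjusted_p == res.p_value

    def test_three_groups_bonferroni_factor(self):
        rng = np.random.default_rng(6)
        x = _frame(rng.normal(size=(12, 4)))
        d = stats.aitchison_distance(x - x.mean(axis=1).to_numpy()[:, None])
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        results = stats.pairwise_permanova(d, labels, n_perm=99, seed=0)
        assert len(results) == 3
        for r in results:
            assert r.adjusted_p == pytest.approx(min(1.0, r.p_value * 3))
            assert r.adjusted_p >= r.p_value


class TestCovariability:
    def test_perfectly_correlated_pair_share_component_one(self):
        t = np.linspace(0, 1, 20)
        x = pd.DataFrame({"u": t, "v": 3 * t + 1})
        res = stats.covariability_pca(x)
        np.testing.assert_allclose(res.r_squared["PC1"].to_numpy(), 1.0,
                                   atol=1e-9)
        assert res.pca.variance_explained[0] == pytest.approx(1.0)

    def test_independent_variable_isolated_on_own_component(self):
        # u, v move together; w is orthogonal to both by construction
        u = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        w = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        res = stats.covariability_pca(pd.DataFrame({"u": u, "v": 2 * u, "w": w}))
        r2 = res.r_squared
        w_comp = r2.loc["w"].idxmax()
        assert r2.loc["w", w_comp] == pytest.approx(1.0)
        assert r2.loc["u", w_comp] == pytest.approx(0.0, abs=1e-9)

    def test_r2_matches_direct_correlation(self):
        rng = np.random.default_rng(7)
        x = pd.DataFrame(rng.normal(size=(25, 5)),
                         columns=list("abcde"))
        res = stats.covariability_pca(x)
        z = (x - x.mean()) / x.std(ddof=1)
        for var in x.columns:
            for comp in res.pca.scores.columns:
                expect = np.corrcoef(z[var], res.pca.scores[comp])[0, 1] ** 2
                assert res.r_squared.loc[var, comp] == pytest.approx(expect,
                                                                     abs=1e-9)

    def test_zero_variance_variable_named_in_error(self):
        x = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            stats.covariability_pca(x)


class TestAnovaTukey:
    def test_identical_constant_groups_degenerate(self):
        res = stats.anova_tukey([3.0] * 6, ["a", "a", "a", "b", "b", "b"])
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0
        assert (res.tukey["p_adj"] == 1.0).all()

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        from scipy.stats import ttest_ind
        res = stats.anova_tukey(np.concatenate([a, b]),
                                ["a"] * 10 + ["b"] * 12)
        t = ttest_ind(a, b).statistic
        assert res.f_statistic == pytest.approx(t ** 2, rel=1e-9)

    def test_anova_matches_manual_decomposition(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=18)
        labels = ["a"] * 5 + ["b"] * 6 + ["c"] * 7
        res = stats.anova_tukey(values, labels)
        # manual one-way decomposition
        groups = {}
        for v, l in zip(values, labels):
            groups.setdefault(l, []).append(v)
        grand = values.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups.values())
        ssw = sum(sum((x - np.mean(g)) ** 2 for x in g) for g in groups.values())
        f = (ssb / 2) / (ssw / 15)
        assert res.f_statistic == pytest.approx(f, rel=1e-9)

    def test_tukey_kramer_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(10)
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 12),
                                 rng.normal(0.5, 1, 5)])
        labels = ["a"] * 8 + ["b"] * 12 + ["c"] * 5
        ours = stats.anova_tukey(values, labels)
        ref = sm.pairwise_tukeyhsd(values, labels)
        np.testing.assert_allclose(ours.tukey["p_adj"].to_numpy(),
                                   ref.pvalues, atol=5e-3)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="2 members"):
            stats.anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])
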