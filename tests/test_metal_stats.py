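"""Correlation, averaging, normalisation and PCA of the metal data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import greentide as gt
from greentide.metals import MetalMatrix, rankdata_average, site_mean_table


def _matrix(values, sites, escs):
    df = pd.DataFrame(values, columns=[f"m{i}" for i in range(np.shape(values)[1])])
    return MetalMatrix(data=df, site=pd.Series(sites), esc=pd.Series(escs))


class TestSiteMeans:
    def test_mean_and_se(self):
        mat = _matrix([[1.0], [3.0], [5.0], [5.0]], ["a", "a", "b", "b"],
                      ["H", "H", "M", "M"])
        means, ses = site_mean_table(mat)
        assert means.loc["a", "m0"] == 2.0
        assert ses.loc["a", "m0"] == pytest.approx(1.0)
        assert ses.loc["b", "m0"] == 0.0

    def test_large_sample_recovers_generator_means(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(np.log(10.0), 0.3, size=(1000, 1))
        mat = _matrix(vals, ["a"] * 1000, ["H"] * 1000)
        means, ses = site_mean_table(mat)
        true_mean = 10.0 * np.exp(0.3 ** 2 / 2)
        assert abs(means.loc["a", "m0"] - true_mean) < 3 * ses.loc["a", "m0"]


class TestSpearman:
    def test_matches_scipy_with_ties(self, metal_site_means, published_eqr):
        for metal in metal_site_means.columns:
            mine = gt.spearman(metal_site_means[metal].values, published_eqr.values)
            ref = sps.spearmanr(metal_site_means[metal].values, published_eqr.values)
            assert mine.coefficient == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_rank_ties_get_average_ranks(self):
        assert list(rankdata_average([10, 20, 20, 30])) == [1.0, 2.5, 2.5, 4.0]

    def test_perfect_and_inverse(self):
        x = np.arange(8.0)
        assert gt.spearman(x, x).coefficient == pytest.approx(1.0)
        assert gt.spearman(x, -x).coefficient == pytest.approx(-1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=20, unique=True),
           st.integers(0, 100))
    def test_monotone_transform_invariance_and_bounds(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.array(xs, dtype=float)
        y = rng.normal(size=len(x))
        r1 = gt.spearman(x, y).coefficient
        r2 = gt.spearman(x ** 3 + 2.0 * x, y).coefficient  # strictly monotone
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert -1.0 <= r1 <= 1.0

    def test_exact_permutation_p_close_to_t_for_moderate_rho(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        y = np.array([2, 1, 4, 3, 6, 5, 8, 7.0])
        exact = gt.spearman(x, y, p_method="exact")
        assert 0.0 < exact.p_value <= 1.0
        t_based = gt.spearman(x, y, p_method="t")
        assert exact.p_value == pytest.approx(t_based.p_value, abs=0.12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="zero variance"):
            gt.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            gt.spearman([1.0, 2.0], [1.0, 2.0])


class TestFisherZ:
    def test_published_mean(self):
        rhos = gt.datasets.load_eqr_correlations().drop("MCI").values
        mean_r, lo, hi = gt.fisher_z_mean(rhos)
        assert mean_r == pytest.approx(-0.43, abs=5e-3)
        assert lo < mean_r < hi

    def test_single_value_identity(self):
        mean_r, lo, hi = gt.fisher_z_mean([0.3])
        assert mean_r == pytest.approx(0.3)
        assert np.isnan(lo) and np.isnan(hi)

    def test_all_zero(self):
        mean_r, lo, hi = gt.fisher_z_mean([0.0, 0.0, 0.0])
        assert mean_r == 0.0 == lo == hi

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            gt.fisher_z_mean([0.5, 1.0])


class TestMetalContentIndex:
    @pytest.mark.parametrize("vals,expected", [([1, 100], 10.0), ([7, 7, 7], 7.0),
                                               ([2, 4, 8], 4.0)])
    def test_geometric_mean(self, vals, expected):
        assert gt.metal_content_index(vals) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gt.metal_content_index([1.0, 0.0])


class TestNormalize:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(size=(30, 4)), columns=list("abcd"))
        z = gt.normalize(df)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_two_sample_hand_value(self):
        z = gt.normalize(pd.DataFrame({"a": [0.0, 2.0]}))
        assert z["a"].tolist() == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20, 3)))
        z = gt.normalize(df)
        assert np.allclose(gt.normalize(z).values, z.values, atol=1e-12)

    def test_zero_variance_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            gt.normalize(df)


class TestDistance:
    def test_hand_values(self):
        d = gt.euclidean_distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(5.0)
        d1 = gt.euclidean_distance_matrix(np.array([0.0, 3.0]))
        assert d1[0, 1] == pytest.approx(3.0)
        same = gt.euclidean_distance_matrix(np.ones((3, 2)))
        assert np.all(same == 0.0)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        d = gt.euclidean_distance_matrix(rng.normal(size=(10, 3)))
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)


class TestPCA:
    def test_perfect_correlation_one_component(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = gt.pca(df)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_variance_sums_and_reconstruction(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(40, 6)))
        res = gt.pca(df)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
        recon = res.scores.values @ res.loadings.values.T
        assert np.allclose(recon, gt.normalize(df).values, atol=1e-9)

    def test_matches_sklearn_on_standardized_data(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.lognormal(size=(30, 5)))
        res = gt.pca(df)
        sk = SkPCA().fit(gt.normalize(df).values)
        # eigenvalues of the correlation matrix vs sklearn's (n-1)-scaled vars
        assert np.allclose(sorted(res.eigenvalues, reverse=True),
                           sk.explained_variance_, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            gt.pca(pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1, 2, 3.0]}))


class TestPearsonMatrix:
    def test_structure(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": -x,
                           "d": rng.normal(size=20)})
        corr = gt.pearson_matrix(df)
        assert np.allclose(np.diag(corr.values), 1.0)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(corr.values, corr.values.T)

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        corr = gt.pearson_matrix(df)
        assert np.isnan(corr.loc["a", "flat"])


class TestAnovaPerMetal:
    def test_disjoint_sites_get_distinct_letters(self):
        vals = np.r_[np.random.default_rng(8).normal(1.0, 0.1, 10),
                     np.random.default_rng(9).normal(10, 0.1, 10)][:, None]
        mat = _matrix(vals, ["a"] * 10 + ["b"] * 10, ["H"] * 10 + ["M"] * 10)
        res = gt.anova_per_metal(mat, n_perm=199, seed=0)
        letters = res.loc["m0", "letters"]
        assert set(letters["a"]).isdisjoint(set(letters["b"]))
        assert res.loc["m0", "p"] < 0.01

    def test_identical_distributions_share_letters(self):
        rng = np.random.default_rng(10)
        vals = rng.lognormal(size=(30, 1))
        mat = _matrix(vals, ["a"] * 10 + ["b"] * 10 + ["c"] * 10, ["H"] * 30)
        res = gt.anova_per_metal(mat, n_perm=199, seed=1)
        letters = res.loc["m0", "letters"]
        assert set(letters["a"]) & set(letters["b"]) & set(letters["c"])

    def test_shifted_site_detected_at_n20(self):
        rng = np.random.default_rng(11)
        a = rng.normal(10.0, 1.0, 20)
        b = rng.normal(10.0, 1.0, 20)
        c = rng.normal(14.0, 1.0, 20)  # large shift
        mat = _matrix(np.r_[a, b, c][:, None],
                      ["a"] * 20 + ["b"] * 20 + ["c"] * 20, ["H"] * 60)
        res = gt.anova_per_metal(mat, n_perm=199, seed=2)
        assert res.loc["m0", "p"] < 0.001
        letters = res.loc["m0", "letters"]
        assert set(letters["c"]).isdisjoint(set(letters["a"]) | set(letters["b"]))


class TestMetalMatrixValidation:
    def test_site_with_two_statuses_rejected(self):
        with pytest.raises(ValueError, match="exactly one status"):
            _matrix([[1.0], [2.0]], ["a", "a"], ["H", "M"])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[-1.0]], ["a"], ["H"])

    def test_from_frame_requires_columns(self):
        df = pd.DataFrame({"sample_id": ["x"], "site_id": ["a"], "Cu": [1.0]})
        with pytest.raises(ValueError, match="esc_label"):
            MetalMatrix.from_frame(df)
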