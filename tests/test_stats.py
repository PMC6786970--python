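"""Dissimilarity, ordination, permutation tests, ratios and PLS."""

import numpy as np
import pandas as pd
import pytest

from soilvirome.stats import (
    GroupRegression,
    accumulation_curve,
    anosim,
    binomial_pervasiveness,
    bonferroni_alpha,
    bray_curtis,
    habitat_regression_anova,
    lineage_sums,
    mantel_spearman,
    metabolism_group_sums,
    pcoa,
    pearson,
    permanova,
    permdisp,
    pls_fit,
    pls_predict,
    prediction_r,
    virus_host_ratio,
)


def _table(cols):
    return pd.DataFrame(cols)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        mat = _table({"s1": [1.0, 2.0], "s2": [1.0, 2.0]})
        assert bray_curtis(mat).loc["s1", "s2"] == 0.0

    def test_disjoint_samples_one(self):
        mat = _table({"s1": [1.0, 0.0], "s2": [0.0, 2.0]})
        assert bray_curtis(mat).loc["s1", "s2"] == 1.0

    def test_hand_arithmetic(self):
        mat = _table({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        assert bray_curtis(mat).loc["x", "y"] == pytest.approx(2 / 6)

    def test_bounded_and_symmetric(self, rng):
        mat = pd.DataFrame(rng.uniform(0, 5, (10, 6)), columns=list("abcdef"))
        d = bray_curtis(mat)
        assert ((d.to_numpy() >= 0) & (d.to_numpy() <= 1)).all()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)


class TestPcoa:
    def test_equilateral_triangle(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        _, eigvals = pcoa(d)
        pos = eigvals[eigvals > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_euclidean_distances_reconstructed(self, rng):
        pts = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)))
        coords, eigvals = pcoa(d)
        recon = squareform(pdist(coords.to_numpy()))
        assert np.allclose(recon, d.to_numpy(), atol=1e-8)

    def test_duplicated_sample_coincident(self, rng):
        pts = rng.normal(size=(5, 2))
        pts = np.vstack([pts, pts[0]])
        from scipy.spatial.distance import pdist, squareform

        coords, _ = pcoa(pd.DataFrame(squareform(pdist(pts))))
        assert np.allclose(coords.iloc[0], coords.iloc[-1], atol=1e-8)


def _null_community(rng, n=30, p=25):
    data = pd.DataFrame(
        rng.lognormal(0, 1, (p, n)), columns=[f"s{i}" for i in range(n)]
    )
    groups = np.repeat(["g1", "g2", "g3"], n // 3)
    return bray_curtis(data), groups


class TestPermutationTests:
    def test_single_group_rejected(self, rng):
        d, _ = _null_community(rng)
        with pytest.raises(ValueError):
            permanova(d, ["g"] * d.shape[0], n_perm=9, seed=0)

    def test_detects_planted_structure(self, rng):
        # two groups dominated by disjoint entity blocks
        base = rng.lognormal(0, 0.3, (20, 20))
        base[:10, :10] *= 6.0  # entities 0-9 bloom in group a samples
        base[10:, 10:] *= 6.0  # entities 10-19 bloom in group b samples
        data = pd.DataFrame(base, columns=[f"s{i}" for i in range(20)])
        groups = ["a"] * 10 + ["b"] * 10
        d = bray_curtis(data)
        assert permanova(d, groups, n_perm=199, seed=1).p_value <= 0.01
        assert anosim(d, groups, n_perm=199, seed=1).p_value <= 0.01

    def test_pvalue_plus_one_rule(self, rng):
        d, groups = _null_community(rng)
        res = permanova(d, groups, n_perm=99, seed=5)
        assert res.p_value * (res.n_permutations + 1) == int(
            res.p_value * (res.n_permutations + 1)
        )
        assert 1 / 100 <= res.p_value <= 1.0

    def test_statistics_match_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        d, groups = _null_community(rng)
        dm = skbio_stats.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        ours = permanova(d, groups, n_perm=9, seed=0).statistic
        theirs = skbio_stats.permanova(dm, list(groups), permutations=9)["test statistic"]
        assert ours == pytest.approx(theirs, rel=1e-9)
        ours_r = anosim(d, groups, n_perm=9, seed=0).statistic
        theirs_r = skbio_stats.anosim(dm, list(groups), permutations=9)["test statistic"]
        assert ours_r == pytest.approx(theirs_r, rel=1e-9)

    def test_permdisp_equal_dispersion_not_significant(self, rng):
        d, groups = _null_community(rng)
        res = permdisp(d, groups, n_perm=199, seed=2)
        assert res.p_value > 0.01  # exchangeable groups: no dispersion signal

    def test_deterministic_under_seed(self, rng):
        d, groups = _null_community(rng)
        a = permanova(d, groups, n_perm=49, seed=7)
        b = permanova(d, groups, n_perm=49, seed=7)
        assert a == b


class TestMantel:
    def test_self_correlation_one(self, rng):
        d, _ = _null_community(rng, n=12)
        res = mantel_spearman(d, d, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        d, _ = _null_community(rng, n=12)
        d2 = d**2  # strictly monotone on [0,1]
        assert mantel_spearman(d, d2, n_perm=99, seed=0).statistic == pytest.approx(1.0)

    def test_independent_matrices_null(self, rng):
        d1, _ = _null_community(rng, n=15)
        d2, _ = _null_community(rng, n=15)
        res = mantel_spearman(d1, d2, n_perm=199, seed=3)
        assert abs(res.statistic) < 0.4
        assert res.p_value > 0.01

    def test_matches_skbio(self, rng):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        d1, _ = _null_community(rng, n=12)
        d2, _ = _null_community(rng, n=12)
        r, _, _ = skbio_dist.mantel(
            skbio_dist.DistanceMatrix(d1.to_numpy()),
            skbio_dist.DistanceMatrix(d2.to_numpy()),
            method="spearman",
            permutations=0,
        )
        assert mantel_spearman(d1, d2, n_perm=9, seed=0).statistic == pytest.approx(r, rel=1e-9)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x)[0] == pytest.approx(1.0)

    def test_constructed_orthogonal(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson(x, y)[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pairs(self):
        r, _ = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_pairwise_complete(self):
        x = np.array([1, 2, 3, 4, np.nan])
        y = np.array([2, 4, 6, 8, 100.0])
        assert pearson(x, y)[0] == pytest.approx(1.0)


class TestHabitatRegression:
    def test_planted_slope_differences(self, rng):
        x = np.tile(np.linspace(0, 1, 20), 3)
        groups = np.repeat(["a", "b", "c"], 20)
        slopes = {"a": 0.2, "b": 1.0, "c": 2.0}
        y = np.array([slopes[g] * xi for g, xi in zip(groups, x)])
        y = y + rng.normal(0, 0.02, y.size)
        fits, res = habitat_regression_anova(x, y, groups, n_perm=199, seed=0)
        assert res.p_value <= 0.01
        fitted_slopes = {f.group: f.slope for f in fits}
        for g, s in slopes.items():
            assert fitted_slopes[g] == pytest.approx(s, abs=0.05)

    def test_identical_slopes_null(self, rng):
        x = np.tile(np.linspace(0, 1, 15), 2)
        groups = np.repeat(["a", "b"], 15)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.1, x.size)
        _, res = habitat_regression_anova(x, y, groups, n_perm=199, seed=1)
        assert res.p_value > 0.05

    def test_small_group_excluded(self, rng):
        x = np.concatenate([np.linspace(0, 1, 10), np.linspace(0, 1, 10), [0.5, 0.6]])
        groups = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 2)
        y = x + rng.normal(0, 0.05, x.size)
        fits, _ = habitat_regression_anova(x, y, groups, n_perm=49, seed=0)
        assert {f.group for f in fits} == {"a", "b"}


class TestAccumulation:
    def test_ubiquitous_entities_flat(self):
        inc = pd.DataFrame(np.ones((5, 4)))
        mean, traces = accumulation_curve(inc, n_rand=20, seed=0)
        assert (mean == 5).all()

    def test_one_entity_per_sample_linear(self):
        inc = pd.DataFrame(np.eye(6))
        mean, _ = accumulation_curve(inc, n_rand=50, seed=0)
        assert np.allclose(mean, np.arange(1, 7))

    def test_final_value_is_total_richness(self, rng):
        inc = pd.DataFrame((rng.random((30, 8)) < 0.3).astype(float))
        richness = (inc.sum(axis=1) > 0).sum()
        mean, traces = accumulation_curve(inc, n_rand=25, seed=1)
        assert (traces[:, -1] == richness).all()


class TestLineageSumsAndRatios:
    LIN = {
        "v1": "d__B;p__P;c__C1",
        "v2": "d__B;p__P;c__C1",
        "h1": "d__B;p__P;c__C1",
    }

    def test_sums_by_class(self):
        ab = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.5, 0.5]}, index=["v1", "v2"])
        sums = lineage_sums(ab, self.LIN, level=2)
        assert sums.loc["d__B;p__P;c__C1", "s1"] == 3.0

    def test_simple_ratio(self):
        v = pd.DataFrame({"s1": [2.0]}, index=["d__B;p__P;c__C1"])
        h = pd.DataFrame({"s1": [4.0]}, index=["d__B;p__P;c__C1"])
        (rec,) = virus_host_ratio(v, h)
        assert rec.mean_ratio == 0.5 and rec.n_samples == 1

    def test_zero_host_sample_excluded(self):
        v = pd.DataFrame({"s1": [2.0], "s2": [2.0]}, index=["L"])
        h = pd.DataFrame({"s1": [4.0], "s2": [0.0]}, index=["L"])
        (rec,) = virus_host_ratio(v, h)
        assert rec.n_samples == 1 and rec.mean_ratio == 0.5

    def test_unlinked_viruses_contribute_nowhere(self):
        ab = pd.DataFrame({"s1": [1.0, 5.0]}, index=["v1", "orphan"])
        sums = lineage_sums(ab, self.LIN, level=2)
        assert sums["s1"].sum() == 1.0

    def test_class_falls_back_to_phylum(self):
        lin = {"x": "d__B;p__P;"}
        ab = pd.DataFrame({"s1": [2.0]}, index=["x"])
        sums = lineage_sums(ab, lin, level=2)
        assert list(sums.index) == ["d__B;p__P"]


class TestMetabolismGroups:
    def test_empty_group_zero_row(self):
        ab = pd.DataFrame({"s1": [1.0]}, index=["h1"])
        sums = metabolism_group_sums(ab, {"methanogens": []})
        assert sums.loc["methanogens", "s1"] == 0.0

    def test_entity_in_two_groups(self):
        ab = pd.DataFrame({"s1": [2.0]}, index=["h1"])
        sums = metabolism_group_sums(ab, {"a": ["h1"], "b": ["h1"]})
        assert sums["s1"].tolist() == [2.0, 2.0]

    def test_toy_table_manual_addition(self):
        ab = pd.DataFrame({"s1": [1.0, 2.0, 4.0]}, index=["h1", "h2", "h3"])
        sums = metabolism_group_sums(ab, {"g": ["h1", "h3"]})
        assert sums.loc["g", "s1"] == 5.0


class TestBinomialAndBonferroni:
    def test_zero_successes(self):
        assert binomial_pervasiveness(0, 100) == 1.0

    def test_all_successes_closed_form(self):
        assert binomial_pervasiveness(5, 5) == pytest.approx(0.05**5)

    def test_direct_summation_oracle(self):
        from math import comb

        k, n, a = 13, 140, 0.05
        expected = sum(comb(n, i) * a**i * (1 - a) ** (n - i) for i in range(k, n + 1))
        assert binomial_pervasiveness(k, n, a) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0237141, abs=1e-6)

    @pytest.mark.parametrize(
        "alpha,n,expected", [(0.05, 41, 0.00122), (0.05, 1, 0.05), (0.10, 4, 0.025)]
    )
    def test_bonferroni(self, alpha, n, expected):
        assert bonferroni_alpha(alpha, n) == pytest.approx(expected, abs=5e-6)


class TestPls:
    def test_exact_linear_recovery(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = 2 * X["a"] - 1 * X["b"]
        model = pls_fit(X, y, n_components=4)  # full rank: equals OLS, exact
        r, _ = prediction_r(model)
        assert r >= 1 - 1e-8

    def test_one_component_exact_on_orthogonal_predictors(self, rng):
        # orthogonalize against the intercept too, so centering is a no-op
        q, _ = np.linalg.qr(np.column_stack([np.ones(30), rng.normal(size=(30, 3))]))
        X = pd.DataFrame(q[:, 1:], columns=list("abc"))
        y = 2 * X["a"] - 1 * X["b"]
        # with orthonormal predictors the first PLS direction spans y exactly
        model = pls_fit(X, y, n_components=1)
        assert prediction_r(model)[0] >= 1 - 1e-8

    def test_coefficient_signs_recovered(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = 3 * X["a"] - 2 * X["b"] + 0.5 * X["c"]
        model = pls_fit(X, y, n_components=3)
        assert np.sign(model.coefficients).tolist() == [1, -1, 1]

    def test_single_column_proportional_to_slope(self, rng):
        x = rng.normal(size=25)
        y = 1.5 * x + rng.normal(0, 0.1, 25)
        model = pls_fit(pd.DataFrame({"x": x}), y, n_components=1)
        slope = np.polyfit(x, y, 1)[0]
        fitted_slope = np.polyfit(x, model.fitted, 1)[0]
        assert fitted_slope == pytest.approx(slope, rel=1e-6)

    def test_scores_orthogonal(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 5)))
        y = rng.normal(size=25)
        model = pls_fit(X, y, n_components=3)
        gram = model.x_scores.T @ model.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_too_many_components_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            pls_fit(X, rng.normal(size=10), n_components=5)

    def test_predict_on_new_data(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = X["a"] - X["c"]
        model = pls_fit(X, y, n_components=3)  # full rank: exact linear map
        Xnew = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        pred = pls_predict(model, Xnew)
        assert np.allclose(pred, Xnew["a"] - Xnew["c"], atol=1e-6)
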