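import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from areadep.domains import (
    DomainRecipe,
    blom_normal_scores,
    build_domain_score,
    fa_indicator_weights,
    minmax_normalize,
    rank_with_mean_ties,
)
from areadep.errors import ConfigurationError, DegenerateScaleError, ValidationError


class TestMeanTieRanking:
    def test_tied_scores_share_mean_positional_rank(self):
        out = rank_with_mean_ties(pd.Series([5.0, 7.0, 7.0, 9.0]))
        assert out.tolist() == [1.0, 2.5, 2.5, 4.0]

    def test_strictly_increasing_input_is_identity(self):
        out = rank_with_mean_ties(pd.Series(np.arange(50, dtype=float)))
        assert out.tolist() == list(range(1, 51))

    def test_matches_sort_then_average_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            x = rng.integers(0, 8, size=rng.integers(3, 40)).astype(float)
            got = rank_with_mean_ties(pd.Series(x)).to_numpy()
            # oracle: positional ranks after a stable sort, averaged over ties
            order = np.argsort(x, kind="stable")
            pos = np.empty(len(x))
            pos[order] = np.arange(1, len(x) + 1)
            want = np.array([pos[x == v].mean() for v in x])
            np.testing.assert_allclose(got, want)

    def test_rank_sum_is_triangular_number(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 5, size=200).astype(float)
        assert rank_with_mean_ties(pd.Series(x)).sum() == 200 * 201 / 2

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError):
            rank_with_mean_ties(pd.Series([1.0, np.nan]))


class TestBlomScores:
    def test_median_rank_maps_to_zero(self):
        assert blom_normal_scores(pd.Series([3.0]), n=5).iloc[0] == pytest.approx(0.0)

    def test_symmetry_about_the_median(self):
        n = 17
        r = pd.Series(np.arange(1.0, n + 1))
        s = blom_normal_scores(r, n)
        np.testing.assert_allclose(s.to_numpy(), -s.to_numpy()[::-1], atol=1e-12)

    def test_top_rank_quantile(self):
        got = blom_normal_scores(pd.Series([5.0]), n=5).iloc[0]
        assert got == pytest.approx(stats.norm.ppf(4.625 / 5.25), abs=1e-10)
        assert got == pytest.approx(1.1798, abs=5e-4)

    def test_out_of_range_rank_rejected(self):
        with pytest.raises(ValidationError):
            blom_normal_scores(pd.Series([6.0]), n=5)


class TestMinMax:
    def test_basic_scaling(self):
        assert minmax_normalize(pd.Series([2.0, 4.0, 6.0])).tolist() == [0.0, 0.5, 1.0]

    def test_arithmetic(self):
        out = minmax_normalize(pd.Series([10.0, 11.0, 15.0, 30.0]))
        assert out.tolist() == pytest.approx([0.0, 0.05, 0.25, 1.0])

    def test_invariant_to_positive_affine_transforms(self):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=30))
        pd.testing.assert_series_equal(minmax_normalize(3.7 * x + 11), minmax_normalize(x))

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateScaleError):
            minmax_normalize(pd.Series([4.0, 4.0]))


def simulate_single_factor(loadings, n, seed):
    """Draw standardized indicators from a one-factor model with given loadings."""
    rng = np.random.default_rng(seed)
    lam = np.asarray(loadings)
    f = rng.normal(size=n)
    eps = rng.normal(size=(n, len(lam))) * np.sqrt(1 - lam**2)
    X = f[:, None] * lam[None, :] + eps
    return pd.DataFrame(X, columns=[f"ind{i}" for i in range(len(lam))])


class TestFactorWeights:
    def test_recovers_closed_form_scoring_coefficients(self):
        # population-level oracle: regression scoring coefficients for one
        # factor are proportional to loading/uniqueness
        lam = np.array([0.9, 0.7, 0.5])
        psi = 1 - lam**2  # (0.19, 0.51, 0.75)
        want = (lam / psi) / (lam / psi).sum()
        np.testing.assert_allclose(want, [0.699, 0.2026, 0.0984], atol=5e-4)
        X = simulate_single_factor(lam, n=20000, seed=1)
        got = fa_indicator_weights(X)
        np.testing.assert_allclose(got.to_numpy(), want, atol=0.03)

    def test_exchangeable_indicators_get_equal_weights(self):
        X = simulate_single_factor([0.7, 0.7, 0.7, 0.7], n=20000, seed=2)
        got = fa_indicator_weights(X)
        np.testing.assert_allclose(got.to_numpy(), 0.25, atol=0.02)

    def test_weight_ordering_follows_loading_ordering(self):
        # mirrors published weight tables: strongest-loading indicator tops
        lam = [0.4, 0.55, 0.65, 0.7, 0.75]
        for seed in range(10):
            X = simulate_single_factor(lam, n=5958, seed=seed)
            w = fa_indicator_weights(X).to_numpy()
            assert (np.diff(w) > 0).all()

    def test_misoriented_indicator_warns_about_negative_coefficient(self):
        X = simulate_single_factor([0.8, 0.7, 0.6], n=5000, seed=3)
        X["ind2"] = -X["ind2"]
        with pytest.warns(UserWarning, match="negative scoring coefficients"):
            fa_indicator_weights(X)

    def test_preconditions(self):
        X = simulate_single_factor([0.8, 0.7, 0.6], n=5000, seed=4)
        with pytest.raises(ConfigurationError):
            fa_indicator_weights(X.iloc[:, :2])
        with pytest.raises(ValidationError):
            fa_indicator_weights(X.head(20))
        X["ind0"] = 1.0
        with pytest.raises(ValidationError, match="constant"):
            fa_indicator_weights(X)


class TestDomainScores:
    def test_housing_weighted_combination_of_normalized_indicators(self):
        # the area at max overcrowding / min renting scores exactly the
        # overcrowding weight
        table = pd.DataFrame(
            {"overcrowding": [0.0, 1.0, 2.0], "renting": [5.0, 3.0, 1.0]},
            index=["A1", "A2", "A3"],
        )
        recipe = DomainRecipe("Housing", "minmax_weighted",
                              ("overcrowding", "renting"), (0.6, 0.4))
        res = build_domain_score(recipe, table)
        assert res.score["A3"] == pytest.approx(0.6)
        assert res.score["A1"] == pytest.approx(0.4)

    def test_single_indicator_domain_keeps_indicator_ranks(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame({"rate": rng.uniform(size=40)})
        recipe = DomainRecipe("Crime", "sum_rate", ("rate",))
        res = build_domain_score(recipe, table)
        pd.testing.assert_series_equal(res.rank, rank_with_mean_ties(table["rate"]))

    def test_fixed_weight_recipe_matches_manual_weighted_sum(self):
        rng = np.random.default_rng(10)
        cols = ["h1", "h2", "h3", "h4", "h5"]
        table = pd.DataFrame(rng.normal(size=(300, 5)), columns=cols)
        weights = (0.04, 0.08, 0.19, 0.28, 0.42)
        recipe = DomainRecipe("Health", "fa_weighted", tuple(cols), weights)
        res = build_domain_score(recipe, table)
        n = len(table)
        manual = sum(
            w * blom_normal_scores(rank_with_mean_ties(table[c]), n)
            for w, c in zip(weights, cols)
        ) / sum(weights)
        pd.testing.assert_series_equal(res.score, manual, check_names=False)

    def test_sum_rate_ranks_invariant_to_increasing_transform(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame({"r1": rng.uniform(0.1, 2, 60)})
        recipe = DomainRecipe("Income", "sum_rate", ("r1",))
        base = build_domain_score(recipe, table)
        warped = build_domain_score(recipe, np.exp(3 * table))
        pd.testing.assert_series_equal(base.rank, warped.rank)

    def test_raising_one_areas_indicator_never_lowers_its_rank(self):
        rng = np.random.default_rng(13)
        cols = ["i1", "i2", "i3"]
        table = pd.DataFrame(rng.normal(size=(80, 3)), columns=cols)
        recipe = DomainRecipe("Health", "fa_weighted", tuple(cols), (0.3, 0.3, 0.4))
        before = build_domain_score(recipe, table)
        bumped = table.copy()
        bumped.iloc[17, 0] += 2.0
        after = build_domain_score(recipe, bumped)
        assert after.rank.iloc[17] >= before.rank.iloc[17]

    def test_rank_conservation_across_recipes(self, small_imd):
        _, intermediates = small_imd
        for res in intermediates["domains"].values():
            assert res.rank.sum() == pytest.approx(res.n * (res.n + 1) / 2)

    def test_method_recipe_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            DomainRecipe("Housing", "minmax_weighted", ("a", "b"))  # no weights
        with pytest.raises(ConfigurationError):
            DomainRecipe("Health", "fa_weighted", ("a", "b"))  # < 3 indicators
        with pytest.raises(ConfigurationError):
            DomainRecipe("Housing", "minmax_weighted", ("a", "b"), (0.5, 0.4))
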