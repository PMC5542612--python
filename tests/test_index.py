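import math

import numpy as np
import pandas as pd
import pytest

from areadep.domains import DomainResult, rank_with_mean_ties
from areadep.errors import CalibrationError, ConfigurationError
from areadep.index import (
    DomainWeightSet,
    ExponentialTransformSpec,
    build_imd,
    calibrate_exponential_constant,
    combine_domains,
    exponential_transform,
    quantile_classify,
)

K_DEFAULT = 50 / math.log(9)


def bisect_constant(top, mid, p, lo=1e-4, hi=1e6, iters=200):
    """Independent bisection oracle for the transform constant."""
    def gap(k):
        return -k * math.log(1 - (1 - p) * (1 - math.exp(-top / k))) - mid

    for _ in range(iters):
        m = 0.5 * (lo + hi)
        if gap(m) < 0:
            lo = m
        else:
            hi = m
    return 0.5 * (lo + hi)


class TestCalibration:
    def test_default_anchors_give_closed_form_constant(self):
        k = calibrate_exponential_constant(ExponentialTransformSpec())
        assert k == pytest.approx(K_DEFAULT, abs=1e-10)
        assert k == pytest.approx(22.756, abs=5e-4)
        assert k == pytest.approx(bisect_constant(100, 50, 0.10), abs=1e-8)

    def test_degenerate_half_tail_has_no_constant(self):
        with pytest.raises(CalibrationError):
            calibrate_exponential_constant(
                ExponentialTransformSpec(top_score=100, mid_score=50, upper_tail=0.5)
            )

    @pytest.mark.parametrize("top,mid,p", [(80.0, 30.0, 0.2), (100.0, 40.0, 0.15), (60.0, 35.0, 0.05)])
    def test_generic_anchors_satisfied_to_high_precision(self, top, mid, p):
        spec = ExponentialTransformSpec(top_score=top, mid_score=mid, upper_tail=p)
        k = calibrate_exponential_constant(spec)
        assert k == pytest.approx(bisect_constant(top, mid, p), rel=1e-8)
        # both anchor conditions hold
        at_tail = -k * math.log(1 - (1 - p) * (1 - math.exp(-top / k)))
        assert at_tail == pytest.approx(mid, abs=1e-10)
        at_top = -k * math.log(math.exp(-top / k))
        assert at_top == pytest.approx(top, abs=1e-10)

    def test_unreachable_mid_anchor_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_exponential_constant(
                ExponentialTransformSpec(top_score=100, mid_score=95, upper_tail=0.1)
            )


class TestExponentialTransform:
    def test_top_rank_maps_to_top_score(self):
        out = exponential_transform(pd.Series([5958.0]), 5958, K_DEFAULT)
        assert out.iloc[0] == pytest.approx(100.0, abs=1e-9)

    def test_tail_boundary_maps_to_mid_score(self):
        out = exponential_transform(pd.Series([0.9 * 5958]), 5958, K_DEFAULT)
        assert out.iloc[0] == pytest.approx(50.0, abs=1e-9)

    def test_median_rank_value(self):
        out = exponential_transform(pd.Series([2979.0]), 5958, K_DEFAULT)
        assert out.iloc[0] == pytest.approx(15.494, abs=1e-3)

    def test_strictly_increasing_in_rank(self):
        ranks = pd.Series(np.arange(1.0, 2001.0))
        s = exponential_transform(ranks, 2000, K_DEFAULT)
        assert (np.diff(s.to_numpy()) > 0).all()

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ConfigurationError):
            exponential_transform(pd.Series([1.0]), 10, 0.0)


class TestQuantiles:
    def test_ten_areas_map_to_their_own_decile(self):
        out = quantile_classify(pd.Series(np.arange(1.0, 11.0)), 10, 10)
        assert out.tolist() == list(range(1, 11))

    def test_full_scale_decile_sizes_are_balanced(self):
        ranks = pd.Series(np.arange(1.0, 5959.0))
        sizes = quantile_classify(ranks, 5958, 10).value_counts()
        assert set(sizes) == {595, 596}

    def test_quintile_nests_decile(self):
        ranks = pd.Series(np.arange(1.0, 101.0))
        dec = quantile_classify(ranks, 100, 10)
        quint = quantile_classify(ranks, 100, 5)
        assert (quint == np.ceil(dec / 2)).all()

    def test_only_quintiles_and_deciles_by_default(self):
        with pytest.raises(ConfigurationError):
            quantile_classify(pd.Series([1.0]), 1, 7)
        assert quantile_classify(pd.Series([1.0, 2.0, 3.0]), 3, 3, allow_any=True).tolist() == [1, 2, 3]


def make_domain(name, scores):
    s = pd.Series(scores, dtype=float)
    return DomainResult(domain=name, score=s, rank=rank_with_mean_ties(s), n=len(s))


class TestCombination:
    def test_identical_transformed_scores_pass_through(self):
        # every domain assigns the same ranks, so the weighted average of
        # identical transformed scores equals those scores
        a = make_domain("Income", [1.0, 2.0, 3.0])
        b = make_domain("Employment", [10.0, 20.0, 30.0])
        ws = DomainWeightSet({"Income": 0.6, "Employment": 0.4})
        res = combine_domains([a, b], ws)
        np.testing.assert_allclose(res.table["imd_score"], res.table["exp_Income"])

    def test_excluding_a_domain_renormalizes_and_follows_survivor(self):
        a = make_domain("Income", [3.0, 1.0, 2.0])
        b = make_domain("Health", [1.0, 2.0, 3.0])
        ws = DomainWeightSet({"Income": 0.7, "Health": 0.3}, exclusions=("Income",))
        assert ws.active().to_dict() == {"Health": 1.0}
        res = combine_domains([b], ws)
        pd.testing.assert_series_equal(res.table["imd_rank"], b.rank, check_names=False)

    def test_matches_hand_computed_weighted_sum(self):
        a = make_domain("Income", [5.0, 1.0, 3.0])   # ranks 3, 1, 2
        b = make_domain("Crime", [2.0, 9.0, 4.0])    # ranks 1, 3, 2
        ws = DomainWeightSet({"Income": 0.8, "Crime": 0.2})
        res = combine_domains([a, b], ws)
        k = res.k
        def t(rank):
            return -k * math.log(1 - rank / 3 * (1 - math.exp(-100 / k)))
        want = [0.8 * t(3) + 0.2 * t(1), 0.8 * t(1) + 0.2 * t(3), t(2)]
        np.testing.assert_allclose(res.table["imd_score"], want, rtol=1e-12)
        # the transform's convexity pushes area 2 (top Crime rank, 20% weight)
        # above area 3 (middling on both domains)
        assert res.table["imd_rank"].tolist() == [3.0, 2.0, 1.0]

    def test_unit_weight_reproduces_single_domain_ranking(self, small_imd):
        result, intermediates = small_imd
        crime = intermediates["domains"]["Crime"]
        ws = DomainWeightSet({"Crime": 1.0})
        solo = combine_domains([crime], ws)
        pd.testing.assert_series_equal(solo.table["imd_rank"], crime.rank, check_names=False)

    def test_weight_for_absent_domain_rejected(self):
        a = make_domain("Income", [1.0, 2.0])
        with pytest.raises(ConfigurationError):
            combine_domains([a], DomainWeightSet({"Income": 0.5, "Health": 0.5}))


class TestEndToEnd:
    def test_invariants_hold_on_synthetic_run(self, small_imd):
        result, _ = small_imd
        t = result.table
        n = result.n
        assert t["imd_rank"].max() == n  # most deprived area carries rank n
        assert t["imd_rank"].sum() == pytest.approx(n * (n + 1) / 2)
        assert t["imd_score"].between(0, 100, inclusive="right").all()
        assert sorted(t["decile"].unique()) == list(range(1, 11))
        assert t.groupby("decile").size().sub(n / 10).abs().max() <= 1
        assert (t["quintile"] == np.ceil(t["decile"] / 2)).all()

    def test_row_order_invariance(self, small_bundle):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(small_bundle.areas))
        res1, _ = build_imd(
            small_bundle.areas, small_bundle.indicator_numerators,
            facilities=small_bundle.facilities, reference_rates=small_bundle.reference_rates,
        )
        res2, _ = build_imd(
            small_bundle.areas.iloc[perm].reset_index(drop=True),
            small_bundle.indicator_numerators.iloc[perm],
            facilities=small_bundle.facilities, reference_rates=small_bundle.reference_rates,
        )
        pd.testing.assert_frame_equal(res1.table.sort_index(), res2.table.sort_index())

    def test_uniform_population_doubling_leaves_ranks_unchanged(self, small_bundle):
        res1, _ = build_imd(
            small_bundle.areas, small_bundle.indicator_numerators,
            facilities=small_bundle.facilities, reference_rates=small_bundle.reference_rates,
        )
        areas2 = small_bundle.areas.copy()
        for c in areas2.columns:
            if c.startswith("pop") or c == "school_leavers":
                areas2[c] = areas2[c] * 2
        res2, _ = build_imd(
            areas2, small_bundle.indicator_numerators * 2,
            facilities=small_bundle.facilities, reference_rates=small_bundle.reference_rates,
        )
        rank_cols = [c for c in res1.table.columns if "rank" in c or c in ("quintile", "decile")]
        pd.testing.assert_frame_equal(res1.table[rank_cols], res2.table[rank_cols])
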