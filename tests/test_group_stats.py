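import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gubquant.group_stats import (
    GroupComparisonResult,
    mann_whitney_u,
    one_way_anova,
    paired_sign_flip,
    paired_t,
    two_sample_t,
    two_way_anova,
)


class TestOneWayAnova:
    def test_hand_computed_toy(self):
        # SSB = 6, SSW = 6, df = (2, 6) -> F = (6/2)/(6/6) = 3.0
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.statistic == pytest.approx(3.0, abs=1e-12)
        assert res.df == (2.0, 6.0)
        assert res.detail["ss_between"] == pytest.approx(6.0)
        assert res.detail["ss_within"] == pytest.approx(6.0)

    def test_identical_groups_null(self):
        res = one_way_anova([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_zero_within_variance_unequal_means(self):
        res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert res.p_value == 0.0
        assert res.significant

    def test_matches_scipy(self, rng):
        groups = [rng.normal(i, 1, size=6) for i in range(3)]
        res = one_way_anova(groups)
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(f_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-10)

    def test_two_groups_f_equals_t_squared(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, size=7)
            y = rng.normal(0.5, 1.3, size=5)
            f_res = one_way_anova([x, y])
            t_res = two_sample_t(x, y, equal_var=True)
            assert f_res.statistic == pytest.approx(t_res.statistic**2, abs=1e-10)
            assert f_res.p_value == pytest.approx(t_res.p_value, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2, 3]])
        with pytest.raises(ValueError):
            one_way_anova([[1, 2], [3]])
        with pytest.raises(ValueError):
            one_way_anova([[1, np.nan], [3, 4]])


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_pooled(self):
        # means 2 and 5, pooled sd = 1, se = sqrt(2/3) -> t = -3/sqrt(2/3)
        res = two_sample_t([1, 2, 3], [4, 5, 6], equal_var=True)
        assert res.statistic == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), rel=1e-12)
        assert res.df == (4.0,)

    def test_welch_equals_pooled_when_balanced(self, rng):
        x = rng.normal(0, 1, 8)
        y = x + 1.0  # identical variances, equal sizes
        pooled = two_sample_t(x, y, equal_var=True)
        welch = two_sample_t(x, y, equal_var=False)
        assert pooled.statistic == pytest.approx(welch.statistic, rel=1e-12)
        assert welch.df[0] == pytest.approx(pooled.df[0], rel=1e-12)

    def test_zero_variance_equal_means(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_matches_scipy(self, rng):
        x = rng.normal(0, 1, 9)
        y = rng.normal(1, 2, 6)
        for equal_var in (True, False):
            res = two_sample_t(x, y, equal_var=equal_var)
            ref = sps.ttest_ind(x, y, equal_var=equal_var)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)


def _enumerate_mw_p(x, y):
    """Independent enumeration oracle: two-sided tail count over labelings."""
    combined = np.concatenate([x, y])
    n1 = len(x)

    def u_of(idx):
        sel = np.asarray(idx)
        xs = combined[sel]
        ys = np.delete(combined, sel)
        u = sum((xs_i > ys).sum() + 0.5 * (xs_i == ys).sum() for xs_i in xs)
        return u

    u_obs = u_of(np.arange(n1))
    u_lo = min(u_obs, n1 * (len(combined) - n1) - u_obs)
    n1n2 = n1 * (len(combined) - n1)
    hits = total = 0
    for picks in itertools.combinations(range(len(combined)), n1):
        u = u_of(list(picks))
        total += 1
        if u <= u_lo + 1e-9 or u >= n1n2 - u_lo - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_fully_separated_small(self):
        # U = 0; 2 of C(6,3)=20 labelings are as extreme -> p = 0.1
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.test_name == "mann_whitney_exact"
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_all_ties(self):
        res = mann_whitney_u([3.0, 3.0, 3.0], [3.0, 3.0])
        assert res.p_value == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 6))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney_u(x, y, exact=True)
            assert res.p_value == pytest.approx(_enumerate_mw_p(x, y), abs=1e-12)

    def test_exact_matches_scipy_no_ties(self, rng):
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            res = mann_whitney_u(x, y, exact=True)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact(self, rng):
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            exact = mann_whitney_u(x, y, exact=True)
            approx = mann_whitney_u(x, y, exact=False)
            assert abs(exact.p_value - approx.p_value) < 0.05

    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=5),
        st.lists(st.integers(0, 50), min_size=1, max_size=5),
    )
    @settings(max_examples=40, deadline=None)
    def test_property_exact_equals_enumeration(self, xs, ys):
        res = mann_whitney_u(xs, ys, exact=True)
        assert 0.0 <= res.p_value <= 1.0
        assert res.p_value == pytest.approx(_enumerate_mw_p(xs, ys), abs=1e-12)


class TestTwoWayAnova:
    def test_matches_statsmodels_balanced(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rows = []
        for a in "pq":
            for b in "uv":
                for _ in range(4):
                    rows.append((rng.normal(ord(a) + 0.5 * ord(b), 1.0), a, b))
        df = pd.DataFrame(rows, columns=["value", "fa", "fb"])
        res = two_way_anova(df["value"], df["fa"], df["fb"])
        table = sm.stats.anova_lm(ols("value ~ C(fa) * C(fb)", data=df).fit(), typ=2)
        assert res["factor_a"].statistic == pytest.approx(table.loc["C(fa)", "F"], rel=1e-8)
        assert res["factor_b"].statistic == pytest.approx(table.loc["C(fb)", "F"], rel=1e-8)
        assert res["interaction"].statistic == pytest.approx(
            table.loc["C(fa):C(fb)", "F"], rel=1e-8
        )

    def test_type_one_error_rate(self):
        hits = 0
        n_rep = 400
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            values = rng.normal(0, 1, 12)
            fa = np.repeat(["a", "b"], 6)
            fb = np.tile(np.repeat(["u", "v"], 3), 2)
            res = two_way_anova(values, fa, fb)
            if res["factor_a"].significant:
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.08

    def test_additive_construction_interaction_small(self):
        rng = np.random.default_rng(11)
        inter_f, main_f = [], []
        for _ in range(100)            :
            fa = np.repeat(["a", "b"], 8)
            fb = np.tile(np.repeat(["u", "v"], 4), 2)
            effect_a = np.where(fa == "a", 0.0, 2.0)
            effect_b = np.where(fb == "u", 0.0, 1.5)
            values = effect_a + effect_b + rng.normal(0, 1, 16)
            res = two_way_anova(values, fa, fb)
            inter_f.append(res["interaction"].statistic)
            main_f.append(res["factor_a"].statistic)
        assert np.mean(inter_f) < np.mean(main_f)

    def test_one_observation_per_cell(self):
        res = two_way_anova([1.0, 2.0, 3.0, 5.0], ["a", "a", "b", "b"], ["u", "v", "u", "v"])
        assert math.isnan(res["interaction"].statistic)
        assert "untestable" in res["interaction"].detail["note"]
        assert math.isfinite(res["factor_a"].statistic)

    def test_unbalanced_restricted_with_warning(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        fa = ["a", "a", "a", "a", "a", "b", "b", "b", "b"]
        fb = ["u", "u", "u", "v", "v", "u", "u", "v", "v"]
        with pytest.warns(UserWarning, match="unbalanced"):
            res = two_way_anova(values, fa, fb)
        assert math.isfinite(res["factor_a"].statistic)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            two_way_anova([1.0, 2.0], ["a", "a"], ["u", "v"])


class TestPairedTests:
    def test_paired_t_identical(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_paired_t_matches_scipy(self, rng):
        x = rng.normal(1, 1, 10)
        y = rng.normal(0, 1, 10)
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_sign_flip_null_case(self):
        res = paired_sign_flip([2.0, 4.0, 1.0], [2.0, 4.0, 1.0])
        assert res.p_value == 1.0

    def test_sign_flip_exact_small(self):
        # d = (1, 1, 1): only the all-positive and all-negative of 8 sign
        # assignments reach |mean| = 1 -> p = 2/8
        res = paired_sign_flip([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(0.25, abs=1e-12)


class TestResultContract:
    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError):
            GroupComparisonResult(test_name="x", statistic=0.0, p_value=1.5)

    def test_verdict_consistency(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.5, 1, 5)
            res = two_sample_t(x, y)
            assert res.significant == (res.p_value < res.alpha)
            assert 0.0 <= res.p_value <= 1.0

    def test_to_dict_roundtrip_fields(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4]])
        d = res.to_dict()
        assert d["test"] == "one_way_anova"
        assert d["verdict"] in ("significant", "not significant")
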