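"""Unit and oracle tests for the shared statistical primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mechanoscreen import stats


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------

class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        res = stats.welch_t_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_closed_form(self):
        # independent evaluation of t = (xa - xb)/sqrt(sa^2/na + sb^2/nb)
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 3, 4, 5, 6])
        se = np.sqrt(a.var(ddof=1) / 5 + b.var(ddof=1) / 5)
        t_expected = (a.mean() - b.mean()) / se
        num = (a.var(ddof=1) / 5 + b.var(ddof=1) / 5) ** 2
        den = (a.var(ddof=1) / 5) ** 2 / 4 + (b.var(ddof=1) / 5) ** 2 / 4
        df_expected = num / den
        res = stats.welch_t_test(a, b)
        assert res.statistic == pytest.approx(t_expected, rel=1e-12)
        assert res.df == pytest.approx(df_expected, rel=1e-12)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_expected), df_expected), rel=1e-12)

    def test_shift_monotonically_decreases_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        ps = [stats.welch_t_test(a, b + c).p for c in (1.0, 2.0, 3.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_zero_variance_degeneracies_flagged(self):
        same = stats.welch_t_test([2, 2, 2], [2, 2, 2])
        assert (same.statistic, same.p, same.flag) == (0.0, 1.0, "zero-variance")
        diff = stats.welch_t_test([2, 2, 2], [3, 3, 3])
        assert diff.p == 0.0 and diff.flag == "zero-variance"

    def test_rejects_tiny_or_nonfinite_samples(self):
        with pytest.raises(ValueError):
            stats.welch_t_test([1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            stats.welch_t_test([1, np.nan, 3], [1, 2, 3])


# ---------------------------------------------------------------------------
# Brown–Forsythe
# ---------------------------------------------------------------------------

class TestBrownForsythe:
    def test_equals_anova_on_median_deviations(self):
        # transform-then-ANOVA oracle
        rng = np.random.default_rng(1)
        for _ in range(10):
            groups = [rng.normal(0, s, size=rng.integers(5, 30))
                      for s in (1.0, 2.0, 0.5)]
            z = [np.abs(g - np.median(g)) for g in groups]
            f_oracle, p_oracle = sps.f_oneway(*z)
            res = stats.brown_forsythe(*groups)
            assert res.statistic == pytest.approx(f_oracle, rel=1e-10)
            assert res.p == pytest.approx(p_oracle, rel=1e-10)

    def test_two_group_w_equals_pooled_t_squared(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0, 3, 40)
        za = np.abs(a - np.median(a))
        zb = np.abs(b - np.median(b))
        t, _ = sps.ttest_ind(za, zb, equal_var=True)
        res = stats.brown_forsythe(a, b)
        assert res.statistic == pytest.approx(t**2, rel=1e-10)

    def test_equal_spread_symmetric_groups_near_zero(self):
        a = np.array([-2.0, -1, 0, 1, 2])
        res = stats.brown_forsythe(a, a + 10)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_all_constant_flagged(self):
        res = stats.brown_forsythe([1, 1, 1], [1, 1, 1])
        assert res.flag == "degenerate"
        assert res.p == 1.0


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

class TestBH:
    def test_worked_example(self):
        # step-up by hand: padj_(i) = min_j>=i m p_(j)/j = 0.04 for all four
        out = stats.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert stats.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(stats.bh_adjust(p), ref)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_monotone_capped_and_order_preserving(self, p):
        padj = stats.bh_adjust(p)
        assert np.all(padj >= np.asarray(p) - 1e-15)
        assert np.all(padj <= 1.0)
        # the adjustment preserves the ranking of the raw p-values
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(padj[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# Gini index
# ---------------------------------------------------------------------------

def _gini_pairwise(x):
    x = np.asarray(x, dtype=float)
    n = x.size
    return np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())


class TestGini:
    def test_uniform_is_zero(self):
        assert stats.gini_index([5, 5, 5, 5]) == pytest.approx(0.0)

    def test_single_nonzero_of_four(self):
        # pairwise oracle: sum|xi-xj| = 2*3*1, 2 n^2 mu = 2*16*0.25 -> 0.75
        assert stats.gini_index([1, 0, 0, 0]) == pytest.approx(0.75)

    def test_sorted_formula_matches_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.integers(0, 1000, size=rng.integers(2, 60)).astype(float)
            if x.sum() == 0:
                x[0] = 1
            assert stats.gini_index(x) == pytest.approx(_gini_pairwise(x), abs=1e-12)

    def test_scale_invariance(self):
        x = [3, 1, 4, 1, 5, 9, 2, 6]
        assert stats.gini_index(x) == pytest.approx(
            stats.gini_index(np.asarray(x) * 1000.0)
        )

    def test_rejects_all_zero_and_negative(self):
        with pytest.raises(ValueError):
            stats.gini_index([0, 0, 0])
        with pytest.raises(ValueError):
            stats.gini_index([1, -1])


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank
# ---------------------------------------------------------------------------

def _logrank_brute(ta, ea, tb, eb):
    """Per-event-time tabulation of observed minus expected in group a."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, int)
    tb, eb = np.asarray(tb, float), np.asarray(eb, int)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(ta.size), np.ones(tb.size)])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(all_t[all_e == 1]):
        at_risk = all_t >= t
        n = at_risk.sum()
        n_a = (at_risk & (grp == 0)).sum()
        d = ((all_t == t) & (all_e == 1)).sum()
        d_a = ((all_t == t) & (all_e == 1) & (grp == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestSurvival:
    def test_km_median_no_censoring(self):
        # S drops to 0.5 exactly at the 5th of 10 events; <=0.5 rule -> 5
        km = stats.km_estimate(np.arange(1, 11), np.ones(10))
        assert km.median == 5.0

    def test_km_all_censored_undefined_median(self):
        km = stats.km_estimate([3, 5, 8], [0, 0, 0])
        assert np.isnan(km.median)
        assert np.all(km.survival == 1.0)

    def test_km_curve_monotone_from_one(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        e[0] = 1
        km = stats.km_estimate(t, e)
        assert km.survival_at(0.0) == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_logrank_matches_brute_force_ten_patients(self):
        ta = [2.0, 4.0, 6.0, 9.0, 12.0]
        ea = [1, 1, 0, 1, 1]
        tb = [1.0, 3.0, 5.0, 7.0, 8.0]
        eb = [1, 1, 1, 0, 1]
        chi2_oracle = _logrank_brute(ta, ea, tb, eb)
        res = stats.logrank_test(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(chi2_oracle, rel=1e-9)
        assert res.p == pytest.approx(sps.chi2.sf(chi2_oracle, 1), rel=1e-9)

    def test_logrank_identical_groups_and_label_swap(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        same = stats.logrank_test(t, e, t, e)
        assert same.statistic == pytest.approx(0.0, abs=1e-12)
        ta, ea = [1.0, 5.0, 7.0], [1, 1, 0]
        tb, eb = [2.0, 3.0, 9.0], [1, 1, 1]
        ab = stats.logrank_test(ta, ea, tb, eb)
        ba = stats.logrank_test(tb, eb, ta, ea)
        assert ab.statistic == pytest.approx(ba.statistic, rel=1e-12)

    def test_logrank_no_events_flagged(self):
        res = stats.logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert res.flag == "no-events" and res.p == 1.0


# ---------------------------------------------------------------------------
# order invariance across tests
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fn", [
    lambda a, b: stats.welch_t_test(a, b).p,
    lambda a, b: stats.brown_forsythe(a, b).p,
])
def test_within_group_order_invariance(fn, rng):
    a = rng.normal(size=20)
    b = rng.normal(size=25)
    assert fn(a, b) == pytest.approx(fn(a[::-1], np.random.default_rng(9).permutation(b)))
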