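"""Hand-built ANOVA / Scheffe / regression against closed forms and an
independent reference implementation (scipy.stats)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from mitomorph import linear_regression, one_way_anova, percent_of_control, scheffe_posthoc
from mitomorph.stats import f_isf, f_sf, sem, t_sf_two_sided


def random_groups(seed, k=4, n=12):
    rng = np.random.default_rng(seed)
    return [rng.normal(rng.uniform(-1, 1), 1.0, n) for _ in range(k)]


class TestAnova:
    def test_identical_constant_groups_are_null(self):
        a = one_way_anova([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert a.f == 0.0
        assert a.p == 1.0
        assert not a.degenerate

    def test_matches_reference_implementation(self):
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        a = one_way_anova(groups)
        ref = ss.f_oneway(*groups)
        assert a.f == pytest.approx(ref.statistic, abs=1e-8)
        assert a.p == pytest.approx(ref.pvalue, abs=1e-8)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 6), n=st.integers(3, 20))
    def test_matches_reference_on_random_groups(self, seed, k, n):
        groups = random_groups(seed, k, n)
        a = one_way_anova(groups)
        ref = ss.f_oneway(*groups)
        assert a.f == pytest.approx(ref.statistic, rel=1e-8)
        assert a.p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_two_groups_equal_squared_t(self):
        g = [[1.0, 2, 3, 5], [2.0, 4, 4, 6]]
        a = one_way_anova(g)
        t = ss.ttest_ind(*g)
        assert a.f == pytest.approx(t.statistic**2)
        assert a.p == pytest.approx(t.pvalue)

    def test_zero_within_variance_with_unequal_means_is_flagged(self):
        a = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert a.degenerate
        assert a.p == 0.0

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestScheffe:
    def test_zero_contrast_never_significant(self):
        g = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]
        contrasts = scheffe_posthoc(one_way_anova(g), g)
        assert contrasts[0].f_scheffe == 0.0
        assert not contrasts[0].significant

    def test_two_group_decision_coincides_with_omnibus(self):
        for seed in range(40):
            g = random_groups(seed, k=2, n=8)
            a = one_way_anova(g)
            (contrast,) = scheffe_posthoc(a, g)
            assert contrast.significant == (a.p <= 0.05)

    def test_all_pairs_match_brute_force_reference(self):
        groups = random_groups(99, k=5, n=10)
        a = one_way_anova(groups)
        contrasts = scheffe_posthoc(a, groups)
        assert len(contrasts) == 10
        crit = (a.k - 1) * ss.f.isf(0.05, a.k - 1, a.n_total - a.k)
        for c in contrasts:
            i, j = c.pair
            gi, gj = np.asarray(groups[i]), np.asarray(groups[j])
            f_ref = (gi.mean() - gj.mean()) ** 2 / (
                a.ms_within * (1 / gi.size + 1 / gj.size))
            assert c.f_scheffe == pytest.approx(f_ref, rel=1e-10)
            assert c.critical == pytest.approx(crit, rel=1e-8)
            assert c.significant == (f_ref > crit)

    def test_mismatched_groups_rejected(self):
        g = random_groups(1, k=3)
        a = one_way_anova(g)
        with pytest.raises(ValueError, match="match"):
            scheffe_posthoc(a, random_groups(2, k=3))


class TestRegression:
    def test_perfect_fit(self):
        x = np.arange(5.0)
        r = linear_regression(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r2 == pytest.approx(1.0)
        assert r.p == 0.0

    def test_closed_form_least_squares(self):
        r = linear_regression([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.slope == pytest.approx(0.6)
        assert r.r == pytest.approx(0.6)
        # t = r sqrt((n-2)/(1-r^2)) consistency
        assert r.t == pytest.approx(r.r * np.sqrt((r.n - 2) / (1 - r.r2)))

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 0.8 * x + rng.normal(size=30)
        r = linear_regression(x, y)
        ref = ss.linregress(x, y)
        assert r.slope == pytest.approx(ref.slope, rel=1e-10)
        assert r.r == pytest.approx(ref.rvalue, rel=1e-10)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-8)

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_joint_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        perm = rng.permutation(12)
        a, b = linear_regression(x, y), linear_regression(x[perm], y[perm])
        assert a.slope == pytest.approx(b.slope)
        assert a.p == pytest.approx(b.p)

    def test_constant_x_is_singular(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            linear_regression([1.0, 2.0], [1.0, 2.0])


class TestTailProbabilities:
    @pytest.mark.parametrize("f,d1,d2", [(2.5, 4, 745), (1.0, 1, 5), (10.0, 2, 30)])
    def test_f_tail_matches_reference_to_1e10(self, f, d1, d2):
        assert f_sf(f, d1, d2) == pytest.approx(ss.f.sf(f, d1, d2), abs=1e-10)

    @pytest.mark.parametrize("t,df", [(1.5, 3), (2.8, 100), (0.2, 8)])
    def test_t_tail_matches_reference_to_1e10(self, t, df):
        assert t_sf_two_sided(t, df) == pytest.approx(2 * ss.t.sf(t, df), abs=1e-10)

    def test_f_quantile_inverts_tail(self):
        q = f_isf(0.05, 4, 745)
        assert f_sf(q, 4, 745) == pytest.approx(0.05, abs=1e-10)


class TestPercentOfControl:
    def test_control_identity(self):
        assert percent_of_control(3.0, 0.3, 3.0) == pytest.approx((100.0, 10.0))

    def test_arithmetic(self):
        assert percent_of_control(2.0, 0.2, 4.0) == pytest.approx((50.0, 5.0))

    @settings(max_examples=50, derandomize=True)
    @given(
        mean=st.floats(0, 100, allow_nan=False),
        err=st.floats(0, 10, allow_nan=False),
        control=st.floats(0.01, 100, allow_nan=False),
    )
    def test_matches_independent_recomputation(self, mean, err, control):
        pct, pct_sem = percent_of_control(mean, err, control)
        assert pct == pytest.approx(100.0 * mean / control)
        assert pct_sem == pytest.approx(100.0 * err / control)

    def test_non_positive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_of_control(1.0, 0.1, 0.0)


def test_sem_matches_definition():
    x = [1.0, 2.0, 4.0, 7.0]
    assert sem(x) == pytest.approx(np.std(x, ddof=1) / 2.0)
    assert sem([3.0]) == 0.0
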