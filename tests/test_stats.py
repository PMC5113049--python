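"""Statistical primitives: t-test, c-statistic, logistic fit, separation
fallback and Bonferroni flags, each checked against an independent route
(closed forms, brute-force pair counting, statsmodels)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirhars.stats_models import (
    bonferroni_flags,
    chisq_fallback_p,
    concordance,
    detect_separation,
    fit_logistic,
    students_t_test,
    _chisq_2x2,
)
from conftest import brute_force_concordance


class TestStudentsT:
    def test_pooled_variance_example(self):
        # {1,2,3} vs {2,3,4}: pooled sd 1, se = sqrt(2/3), df 4
        res = students_t_test([1, 2, 3], [2, 3, 4])
        assert res.t_stat == pytest.approx(-1.2247, abs=1e-4)
        assert res.t_p == pytest.approx(0.2878, abs=1e-4)
        assert (res.n_case, res.n_ref) == (3, 3)
        assert (res.minimum, res.maximum) == (1.0, 4.0)

    def test_identical_groups_degenerate(self):
        res = students_t_test([5, 6], [5, 6])
        assert res.t_stat == 0.0 and res.t_p == 1.0

    def test_all_identical_values_p_one_flagged(self):
        res = students_t_test([5, 5], [5, 5])
        assert res.t_p == 1.0 and res.degenerate

    def test_zero_variance_shifted_groups_p_zero(self):
        res = students_t_test([5, 5, 5], [9, 9, 9])
        assert res.t_p == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            students_t_test([1.0], [2.0, 3.0])

    def test_agrees_with_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(2, 12))
            y = rng.normal(0.5, 2, rng.integers(2, 12))
            res = students_t_test(x, y)
            t, p = stats.ttest_ind(x, y, equal_var=True)
            assert res.t_stat == pytest.approx(t, rel=1e-10)
            assert res.t_p == pytest.approx(p, rel=1e-10)


class TestConcordance:
    @pytest.mark.parametrize(
        "cases,ctrls,expected",
        [
            ([3, 4], [1, 2], 1.0),  # complete separation
            ([2, 2], [2, 2], 0.5),  # all ties
            ([1, 3], [2, 2], 0.5),  # 2 concordant + 2 discordant of 4 pairs
        ],
    )
    def test_examples(self, cases, ctrls, expected):
        scores = cases + ctrls
        y = [1] * len(cases) + [0] * len(ctrls)
        assert concordance(scores, y) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            concordance([1, 2], [1, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 9), min_size=2, max_size=50),
        st.data(),
    )
    def test_matches_brute_force_pair_counting(self, scores, data):
        # Discrete scores force plenty of ties; labels must hit both classes.
        n = len(scores)
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda v: 0 < sum(v) < n
            )
        )
        assert concordance(scores, y) == pytest.approx(
            brute_force_concordance(scores, y), abs=1e-12
        )


class TestSeparation:
    @pytest.mark.parametrize(
        "cases,ctrls,expected",
        [
            ([3, 4], [1, 2], True),
            ([1, 3], [2, 4], False),  # interleaved
            ([2, 3], [1, 2], False),  # boundary tie breaks separation
        ],
    )
    def test_ordering(self, cases, ctrls, expected):
        x = cases + ctrls
        y = [1] * len(cases) + [0] * len(ctrls)
        assert detect_separation(x, y) is expected


class TestChisqFallback:
    def test_perfect_split_table(self):
        # classes {6..10} vs {1..5}: median split gives [[5,0],[0,5]]
        x = [6, 7, 8, 9, 10, 1, 2, 3, 4, 5]
        y = [1] * 5 + [0] * 5
        stat, p, deg = _chisq_2x2(np.array([[5, 0], [0, 5]]))
        assert stat == pytest.approx(10.0)
        assert chisq_fallback_p(x, y) == pytest.approx(0.001565, abs=1e-5)
        assert not deg

    def test_independent_table_p_one(self):
        x = [1, 1, 3, 3, 1, 1, 3, 3]
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        assert chisq_fallback_p(x, y) == pytest.approx(1.0)

    def test_three_one_table(self):
        stat, p, _ = _chisq_2x2(np.array([[3, 1], [1, 3]]))
        assert stat == pytest.approx(2.0)
        assert p == pytest.approx(0.1573, abs=1e-4)
        x = [3, 3, 3, 1, 3, 1, 1, 1]
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        assert chisq_fallback_p(x, y) == pytest.approx(p, abs=1e-12)

    def test_degenerate_margin_p_one(self):
        _, p, deg = _chisq_2x2(np.array([[0, 3], [0, 5]]))
        assert p == 1.0 and deg


class TestLogisticFit:
    def test_dichotomous_predictor_matches_2x2_odds_ratio(self):
        # cases: 4 exposed + 1 unexposed; controls: 1 exposed + 4 unexposed
        x = [1] * 4 + [0] * 1 + [1] * 1 + [0] * 4
        y = [1] * 5 + [0] * 5
        fit = fit_logistic(x, y)
        assert fit.or_value == pytest.approx(16.0, rel=1e-6)
        assert fit.p_source == "wald" and not fit.separated

    def test_constant_predictor_carries_no_information(self):
        fit = fit_logistic([2.0] * 6, [1, 1, 1, 0, 0, 0])
        assert fit.beta1 == 0.0 and fit.or_value == 1.0
        assert fit.concordance == 0.5

    def test_perfect_separation_uses_fallback(self):
        fit = fit_logistic([3, 4, 1, 2], [1, 1, 0, 0])
        assert fit.separated
        assert fit.concordance == 1.0
        assert fit.p_source == "chisq_fallback"
        assert fit.wald_p is None and fit.or_value is None

    def test_separation_implies_no_wald_p(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            ctrl = rng.normal(0, 1, 5)
            case = rng.normal(0, 1, 5) + 10  # far-shifted: always separated
            x = np.concatenate([case, ctrl])
            y = np.array([1] * 5 + [0] * 5)
            assert detect_separation(x, y)
            fit = fit_logistic(x, y)
            assert fit.separated and fit.p_source == "chisq_fallback"
            assert fit.wald_p is None

    def test_matches_statsmodels_on_random_data(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 15:
            n = int(rng.integers(12, 40))
            x = rng.normal(0, 1, n)
            logit = -0.3 + 1.1 * x
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
            if y.sum() in (0, n) or detect_separation(x, y):
                continue
            fit = fit_logistic(x, y)
            if fit.separated:
                continue
            X = sm.add_constant(x)
            ref = sm.Logit(y, X).fit(disp=0)
            assert fit.beta0 == pytest.approx(ref.params[0], abs=1e-5)
            assert fit.beta1 == pytest.approx(ref.params[1], abs=1e-5)
            assert fit.wald_p == pytest.approx(ref.pvalues[1], abs=1e-5)
            checked += 1
        assert checked == 15

    def test_concordance_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        y = (rng.random(20) < 0.5).astype(int)
        if y.sum() in (0, 20):
            y[0] = 1 - y[0]
        f1 = fit_logistic(x, y)
        f2 = fit_logistic(3.7 * x - 11.0, y)
        assert f1.concordance == pytest.approx(f2.concordance, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([1.0, 2.0], [1, 1])


class TestBonferroni:
    @pytest.mark.parametrize(
        "m,expected",
        [(20, 0.0025), (15, 0.05 / 15), (1, 0.05)],
    )
    def test_thresholds(self, m, expected):
        thr, _ = bonferroni_flags([0.01] * m)
        assert thr == pytest.approx(expected)

    def test_strict_inequality(self):
        thr, flags = bonferroni_flags([0.0025, 0.0024] + [0.5] * 18)
        assert thr == pytest.approx(0.0025)
        assert flags[0] is False and flags[1] is True

    def test_threshold_monotone_in_family_size(self):
        thrs = [bonferroni_flags([0.5] * m)[0] for m in range(1, 30)]
        assert all(a > b for a, b in zip(thrs, thrs[1:]))

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_flags([])
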