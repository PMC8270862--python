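"""Variance components, ICC, wSD/wCV, SDD, RMSCV, CCC, SMD, responsiveness."""

import numpy as np
import pandas as pd
import pytest

from synodce.stats import (SDD_FACTOR, icc_confint, icc_from_components,
                           lin_ccc, repeatability_summary, responsiveness_count,
                           rmscv, select_variability_scale,
                           smallest_detectable_difference,
                           standardized_mean_difference,
                           variance_components_oneway, within_subject_cv,
                           within_subject_sd)


def simulate_test_retest(rng, n, mean, sigma_b, sigma_w):
    level = mean + rng.normal(0, sigma_b, n)
    return (level + rng.normal(0, sigma_w, n),
            level + rng.normal(0, sigma_w, n))


class TestVarianceComponents:
    def test_perfect_repeatability_gives_zero_within(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        sb, sw = variance_components_oneway((y, y.copy()))
        assert sw == 0.0
        assert sb == pytest.approx(np.var(y, ddof=1), rel=1e-12)

    def test_constant_visit_difference(self):
        # every subject shifts by d: wSD = |d|/sqrt(2) (two-replicate ANOVA)
        y1 = np.array([1.0, 5.0, 9.0, 2.0])
        d = 0.6
        wsd = within_subject_sd((y1, y1 + d))
        assert wsd == pytest.approx(d / np.sqrt(2), rel=1e-12)

    def test_null_subject_effect_truncated_to_zero(self, rng):
        trunc = 0
        for _ in range(100):
            y1 = rng.normal(0, 1, 20)
            y2 = rng.normal(0, 1, 20)  # no subject effect at all
            sb, _ = variance_components_oneway((y1, y2))
            trunc += sb == 0.0
        assert trunc > 30  # truncation occurs in a large fraction of nulls

    def test_monte_carlo_recovery_at_reported_truth(self, rng):
        sb_t, sw_t = 2.1e-4, 2.4e-5
        y1, y2 = simulate_test_retest(rng, 1000, 0.039, np.sqrt(sb_t),
                                      np.sqrt(sw_t))
        sb, sw = variance_components_oneway((y1, y2))
        assert sb == pytest.approx(sb_t, rel=0.10)
        assert sw == pytest.approx(sw_t, rel=0.10)

    def test_missing_visit_excluded_with_warning(self):
        df = pd.DataFrame({"value_visit1": [1, 2, 3, np.nan],
                           "value_visit2": [1.1, 2.2, 2.9, 4.0]})
        with pytest.warns(UserWarning, match="missing"):
            sb, sw = variance_components_oneway(df)
        assert np.isfinite(sb) and np.isfinite(sw)

    def test_fewer_than_three_subjects_errors(self):
        with pytest.raises(ValueError):
            variance_components_oneway((np.ones(2), np.ones(2)))

    def test_cross_check_against_pingouin_icc1(self, rng):
        pg = pytest.importorskip("pingouin")
        y1, y2 = simulate_test_retest(rng, 25, 10.0, 2.0, 0.8)
        sb, sw = variance_components_oneway((y1, y2))
        long = pd.DataFrame({
            "subject": np.tile(np.arange(25), 2),
            "rater": np.repeat(["a", "b"], 25),
            "y": np.concatenate([y1, y2])})
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="y")
        icc1 = ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0]
        assert icc_from_components(sb, sw) == pytest.approx(icc1, abs=1e-6)


class TestICC:
    @pytest.mark.parametrize("sb,sw,expected", [
        (2.1e-4, 2.4e-5, 0.90),
        (4.2, 2.4, 0.64),
        (2.1e-5, 1.3e-5, 0.62),
    ])
    def test_reported_variance_component_pairs(self, sb, sw, expected):
        assert round(icc_from_components(sb, sw), 2) == expected

    def test_zero_within_variance_gives_one(self):
        assert icc_from_components(3.7, 0.0) == 1.0

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            icc_from_components(0.0, 0.0)

    def test_monotone_in_between_subject_variance(self):
        iccs = [icc_from_components(sb, 1.0) for sb in (0.1, 1.0, 10.0)]
        assert iccs == sorted(iccs)
        assert all(0 <= i <= 1 for i in iccs)

    def test_confint_brackets_point_estimate(self, rng):
        y1, y2 = simulate_test_retest(rng, 15, 5.0, 1.0, 0.5)
        icc, lo, hi = icc_confint((y1, y2))
        assert 0 <= lo <= icc <= hi <= 1


class TestWithinSubjectCV:
    def test_proportional_change_is_scale_free(self):
        y1 = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        a = within_subject_cv((y1, 1.1 * y1))
        b = within_subject_cv((10 * y1, 11 * y1))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_differences_give_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert within_subject_cv((y, y.copy())) == 0.0

    def test_lognormal_cv_recovery(self, rng):
        # true within-subject CV 10%
        n = 500
        mu = rng.normal(3.0, 0.3, n)
        y1 = np.exp(mu) * np.exp(rng.normal(0, 0.0998, n))
        y2 = np.exp(mu) * np.exp(rng.normal(0, 0.0998, n))
        assert within_subject_cv((y1, y2)) == pytest.approx(10.0, abs=1.5)

    def test_nonpositive_mean_errors(self):
        with pytest.raises(ValueError):
            within_subject_cv((np.array([1.0, -2.0, 3.0]),
                               np.array([1.0, 2.0, 3.0])))


class TestScaleSelection:
    def test_variability_proportional_to_magnitude_selects_relative(self):
        y1 = np.linspace(1, 20, 20)
        y2 = y1 * 1.2                     # |difference| proportional to mean
        assert select_variability_scale((y1, y2)) == "relative"

    def test_constant_differences_select_absolute(self):
        y1 = np.linspace(1, 20, 20)
        assert select_variability_scale((y1, y1 + 0.5)) == "absolute"

    def test_type_one_error_rate_near_alpha(self, rng):
        absolute = 0
        for _ in range(200):
            y1 = rng.normal(50, 10, 500)
            y2 = y1 + rng.normal(0, 1, 500)   # variability independent of mean
            absolute += select_variability_scale((y1, y2)) == "absolute"
        assert absolute >= 188  # >= 94% of replicates keep the absolute scale


class TestSDD:
    def test_factor_is_sqrt2_times_196(self):
        assert SDD_FACTOR == pytest.approx(2.7719, abs=1e-4)

    def test_reported_wsd_example(self):
        wsd = np.sqrt(1.3e-5)
        assert round(smallest_detectable_difference(wsd), 3) == 0.010

    def test_reported_wcv_example(self):
        assert smallest_detectable_difference(8.5, "relative") == pytest.approx(
            23.5, abs=0.1)

    def test_zero_input(self):
        assert smallest_detectable_difference(0.0) == 0.0


class TestRMSCV:
    def test_identical_pairs_give_zero(self):
        assert rmscv(np.array([[3.0, 3.0], [7.0, 7.0]])) == 0.0

    def test_hand_computed_single_pair_value(self):
        # pairs (9, 11) and (9, 11): each CV = sqrt(2)/10
        assert rmscv(np.array([[9.0, 11.0], [9.0, 11.0]])) == pytest.approx(
            10 * np.sqrt(2), rel=1e-12)

    def test_scale_invariance(self, rng):
        pairs = rng.uniform(5, 10, (20, 2))
        assert rmscv(pairs) == pytest.approx(rmscv(pairs * 7.3), rel=1e-12)


class TestCCC:
    def test_perfect_concordance(self, rng):
        x = rng.normal(0, 1, 50)
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_perfect_discordance_zero_mean(self, rng):
        x = rng.normal(0, 1, 50)
        x -= x.mean()
        assert lin_ccc(x, -x) == pytest.approx(-1.0)

    def test_location_shift_penalty_closed_form(self, rng):
        x = rng.normal(0, 2, 2000)
        c = 1.5
        got = lin_ccc(x, x + c)
        want = 2 * x.var() / (2 * x.var() + c**2)
        assert got == pytest.approx(want, rel=1e-12)
        assert got < 1.0

    def test_never_exceeds_pearson_magnitude(self, rng):
        x = rng.normal(0, 1, 100)
        y = 0.5 * x + rng.normal(2.0, 0.5, 100)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(lin_ccc(x, y)) <= abs(r) + 1e-12


class TestSMD:
    def test_identical_means_give_zero(self, rng):
        a = rng.normal(5, 1, 30)
        assert standardized_mean_difference(a, a).smd == 0.0

    def test_unit_effect(self):
        a = np.array([0.0, 2.0])   # mean 1, sd sqrt(2)
        b = np.array([-1.0, 1.0])  # mean 0, sd sqrt(2)
        assert standardized_mean_difference(a, b).smd == pytest.approx(
            1 / np.sqrt(2))

    def test_monte_carlo_recovery_of_reported_effect(self, rng):
        # constructed true SMD of 0.94 (reported Ktrans group separation)
        a = rng.normal(0.94, 1.0, 10_000)
        b = rng.normal(0.0, 1.0, 10_000)
        assert standardized_mean_difference(a, b).smd == pytest.approx(
            0.94, abs=0.05)

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError):
            standardized_mean_difference(np.ones(5), np.ones(5))


class TestResponsiveness:
    def test_no_exceedances(self):
        assert responsiveness_count(np.array([0.1, -0.2]), sdd=0.5) == 0

    def test_constructed_counts(self):
        s = 0.3
        d = np.array([2 * s, -2 * s, 0.5 * s])
        assert responsiveness_count(d, sdd=s) == 2

    def test_relative_scale_uses_percent_of_baseline(self):
        d = np.array([0.5, 0.05])
        base = np.array([1.0, 1.0])
        assert responsiveness_count(d, sdd=20.0, scale="relative",
                                    baselines=base) == 1


class TestRepeatabilitySummary:
    def test_summary_consistency(self, rng):
        y1, y2 = simulate_test_retest(rng, 50, 0.039, np.sqrt(2.1e-4),
                                      np.sqrt(2.4e-5))
        m = repeatability_summary((y1, y2), oa_values=y1)
        assert m.icc == pytest.approx(
            icc_from_components(m.sigma_b2, m.sigma_w2))
        assert m.sdd == pytest.approx(SDD_FACTOR * m.wsd_or_wcv)
        assert m.icc_lo <= m.icc <= m.icc_hi
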