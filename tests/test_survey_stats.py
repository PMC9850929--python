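"""Survey descriptives and significance tests on household cohorts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from openburn import survey_stats as ss
from openburn.synthetic_data import SurveyGenSpec, gen_households
from openburn.types import HouseholdRecord

from conftest import make_household
import published_values as pub


class TestWeeklySummary:
    def test_hand_computed_mean_and_sample_sd(self, two_households):
        out = ss.weekly_summary(two_households)
        assert out[0] == (pytest.approx(3.0), pytest.approx(math.sqrt(2)))

    def test_identical_households_have_zero_sd(self):
        recs = [make_household(f"H{i}") for i in range(5)]
        for mean, sd in ss.weekly_summary(recs):
            assert mean == pytest.approx(1.0)
            assert sd == 0.0

    def test_recovers_generator_weekly_targets(self, default_cohort):
        out = ss.weekly_summary(default_cohort)
        n = len(default_cohort)
        for (mean, sd), (target_mean, target_sd) in zip(out, pub.WEEKLY):
            assert abs(mean - target_mean) < 3 * sd / math.sqrt(n)

    def test_missing_week_excluded_not_zero_filled(self, two_households,
                                                   missing_week_household):
        out = ss.weekly_summary(two_households + [missing_week_household])
        # week 2: only the two complete households (1.0, 1.0) remain
        assert out[1] == (pytest.approx(1.0), pytest.approx(0.0))

    def test_empty_and_single_household_rejected(self):
        with pytest.raises(ValueError):
            ss.weekly_summary([])
        with pytest.raises(ValueError):
            ss.weekly_summary([make_household()])


class TestPerCapitaDaily:
    def test_direct_arithmetic(self):
        rec = make_household(persons=6, masses=(1.31, 1.12, 0.92, 0.99))
        mean, sd = ss.per_capita_daily([rec])
        assert mean == pytest.approx(4.34 / (6 * 28))
        assert sd == 0.0

    def test_all_zero_masses(self):
        recs = [make_household(f"H{i}", masses=(0, 0, 0, 0)) for i in range(3)]
        assert ss.per_capita_daily(recs) == (0.0, 0.0)

    def test_missing_weeks_shrink_the_denominator(self, missing_week_household):
        mean, _ = ss.per_capita_daily([missing_week_household])
        assert mean == pytest.approx(4.0 / (3 * 7 * 3))

    def test_recovers_generator_rate(self, default_cohort):
        spec = SurveyGenSpec()
        mean, sd = ss.per_capita_daily(default_cohort)
        se = sd / math.sqrt(len(default_cohort))
        assert abs(mean - spec.expected_per_capita_daily) < 3 * se

    def test_burn_only_filter(self, two_households):
        mean, sd = ss.per_capita_daily(two_households, burn_only=True)
        assert mean == pytest.approx(5.0 / (4 * 28))

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.1, 50), seed=st.integers(0, 2**20))
    def test_reorder_invariant_and_linear_in_mass(self, scale, seed):
        rng = np.random.default_rng(seed)
        recs = [
            make_household(f"H{i}", persons=int(rng.integers(1, 9)),
                           masses=tuple(rng.uniform(0.1, 3.0, 4)))
            for i in range(6)
        ]
        base = ss.per_capita_daily(recs)
        shuffled = ss.per_capita_daily(recs[::-1])
        assert shuffled == pytest.approx(base)
        scaled_recs = [
            make_household(r.household_id, persons=r.persons,
                           masses=tuple(m * scale for m in r.weekly_masses_kg))
            for r in recs
        ]
        scaled = ss.per_capita_daily(scaled_recs)
        assert scaled[0] == pytest.approx(base[0] * scale)
        assert scaled[1] == pytest.approx(base[1] * scale)


class TestLogTTest:
    def test_same_week_gives_p_one(self, default_cohort):
        diff, p = ss.log_ttest_weeks(default_cohort, 2, 2)
        assert diff == 0.0 and p == 1.0

    def test_matches_direct_welch_on_logs(self, default_cohort):
        mat = np.array([[m for m in r.weekly_masses_kg] for r in default_cohort])
        log_a = np.log(mat[:, 0][mat[:, 0] > 0])  # zeros excluded, as documented
        log_b = np.log(mat[:, 2][mat[:, 2] > 0])
        expected = stats.ttest_ind(log_a, log_b, equal_var=False)
        diff, p = ss.log_ttest_weeks(default_cohort, 1, 3)
        assert p == pytest.approx(expected.pvalue)
        assert diff == pytest.approx(log_a.mean() - log_b.mean())

    def test_zero_masses_excluded_then_error_when_too_few(self):
        recs = [make_household(f"H{i}", masses=(0.0, 1.0, 1.0, 1.0))
                for i in range(3)]
        with pytest.raises(ValueError):
            ss.log_ttest_weeks(recs, 1, 2)

    def test_power_matches_noncentral_t_oracle(self):
        """Rejection rate under a log-mean shift matches the noncentral-t power."""
        n, sigma, shift, alpha, reps = 50, 0.8, 0.5, 0.05, 3000
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(reps):
            a = np.exp(rng.normal(shift, sigma, n))
            b = np.exp(rng.normal(0.0, sigma, n))
            recs = [make_household(f"H{i}", masses=(a[i], b[i], 1.0, 1.0))
                    for i in range(n)]
            _, p = ss.log_ttest_weeks(recs, 1, 2)
            rejections += p < alpha
        df = 2 * n - 2
        delta = shift / (sigma * math.sqrt(2 / n))
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        power = 1 - stats.nct.cdf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta)
        assert abs(rejections / reps - power) < 0.03


class TestGroupTests:
    def test_constant_covariate_rejected(self):
        recs = [make_household(f"H{i}", color_tv=True) for i in range(4)]
        with pytest.raises(ValueError):
            ss.group_tests(recs, "color_tv")

    def test_small_group_rejected_with_name(self):
        recs = [make_household(f"H{i}", radio=(i == 0)) for i in range(5)]
        with pytest.raises(ValueError, match="radio"):
            ss.group_tests(recs, "radio")

    def test_recovers_injected_tv_effect(self, default_cohort):
        res = ss.group_tests(default_cohort, "color_tv")
        owners = [r.total_mass_kg for r in default_cohort if r.color_tv]
        others = [r.total_mass_kg for r in default_cohort if not r.color_tv]
        se = math.sqrt(np.var(owners, ddof=1) / len(owners)
                       + np.var(others, ddof=1) / len(others))
        assert res.test == "t-test"
        assert abs(res.difference_kg - (-1.21)) < 3 * se

    def test_education_uses_anova(self, default_cohort):
        res = ss.group_tests(default_cohort, "education")
        assert res.test == "ANOVA"
        assert 0.0 <= res.p_value <= 1.0
        assert res.difference_kg >= 0.0

    def test_null_p_values_uniform(self):
        """With identical group distributions the p-value is U(0,1)."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(400):
            masses = np.exp(rng.normal(0.0, 0.5, (40, 4)))
            flags = rng.random(40) < 0.5
            if flags.sum() < 2 or (~flags).sum() < 2:
                continue
            recs = [make_household(f"H{i}", masses=tuple(masses[i]),
                                   radio=bool(flags[i])) for i in range(40)]
            pvals.append(ss.group_tests(recs, "radio").p_value)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestSizeCorrelation:
    def test_exact_proportionality_gives_r_one(self):
        recs = [make_household(f"H{i}", persons=i + 1,
                               masses=(0.5 * (i + 1),) * 4) for i in range(5)]
        r, _ = ss.size_correlation(recs)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        recs = [make_household(f"H{i}", persons=4,
                               masses=(1.0 + i, 1.0, 1.0, 1.0)) for i in range(4)]
        with pytest.raises(ValueError):
            ss.size_correlation(recs)

    def test_null_critical_value_frequency(self):
        """|r| exceeds the alpha=0.05 critical value about 5% of the time under
        independence (r_crit = 0.279 at n = 50)."""
        rng = np.random.default_rng(33)
        n, reps, r_crit = 50, 2000, 0.2787
        exceed = 0
        for _ in range(reps):
            recs = [make_household(f"H{i}", persons=int(rng.integers(1, 10)),
                                   masses=tuple(rng.uniform(0.1, 2.0, 4)))
                    for i in range(n)]
            r, _ = ss.size_correlation(recs)
            exceed += abs(r) > r_crit
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(exceed / reps - 0.05) < 4 * se

    def test_recovers_injected_negative_correlation(self):
        """A latent size-mass correlation shows up as a negative Pearson r,
        consistent across independent replicates."""
        spec_a = SurveyGenSpec(n_households=50_000, seed=1, size_mass_rho=-0.08)
        spec_b = SurveyGenSpec(n_households=50_000, seed=2, size_mass_rho=-0.08)
        r_a, _ = ss.size_correlation(gen_households(spec_a))
        r_b, _ = ss.size_correlation(gen_households(spec_b))
        assert r_a < -0.04 and r_b < -0.04
        assert abs(r_a - r_b) < 6 / math.sqrt(50_000)


class TestBurningShares:
    def test_all_burners(self):
        recs = [make_household(f"H{i}", burn=True) for i in range(3)]
        assert ss.burning_shares(recs) == (1.0, 1.0)

    def test_hand_computed_shares(self):
        recs = [make_household("A", masses=(3, 0, 0, 0), burn=True),
                make_household("B", masses=(1, 0, 0, 0), burn=False)]
        assert ss.burning_shares(recs) == (0.5, 0.75)

    def test_mass_fraction_is_one_when_nonburners_have_zero_mass(self):
        recs = [make_household("A", masses=(2, 1, 1, 1), burn=True),
                make_household("B", masses=(0, 0, 0, 0), burn=False)]
        assert ss.burning_shares(recs)[1] == 1.0

    def test_default_cohort_near_84_percent(self, default_cohort):
        hh, mass = ss.burning_shares(default_cohort)
        n = len(default_cohort)
        se = math.sqrt(0.84 * 0.16 / n)
        assert abs(hh - 0.84) < 3 * se
        # burning independent of mass -> mass share tracks household share
        assert abs(mass - 0.84) < 5 * se

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ss.burning_shares([])


class TestCsvRoundTrip:
    def test_round_trip_preserves_records(self, tmp_path, default_cohort):
        path = tmp_path / "households.csv"
        subset = default_cohort[:20]
        ss.write_households_csv(subset, path)
        loaded = ss.read_households_csv(path)
        assert loaded == subset

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("household_id,persons\nA,3\n")
        with pytest.raises(ValueError, match="missing columns"):
            ss.read_households_csv(path)

    def test_missing_week_round_trips_as_nan(self, tmp_path, missing_week_household):
        path = tmp_path / "households.csv"
        ss.write_households_csv([missing_week_household] * 2, path)
        loaded = ss.read_households_csv(path)
        assert math.isnan(loaded[0].weekly_masses_kg[1])


def test_record_validation():
    with pytest.raises(ValueError):
        HouseholdRecord("X", 0, (1, 1, 1, 1), True)
    with pytest.raises(ValueError):
        HouseholdRecord("X", 2, (1, 1, 1), True)
    with pytest.raises(ValueError):
        HouseholdRecord("X", 2, (1, 1, 1, -0.5), True)
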