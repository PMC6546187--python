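import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rosscea import (
    CohortStudy,
    NoDataError,
    SimulationProfile,
    compare_arms,
    generate_cohorts,
    pool_proportion,
    pool_rates,
    pooled_table,
    rate_to_probability,
    read_cohort_csv,
    write_cohort_csv,
)


def study(study_id="s1", arm="ross", n=1000, py=1000.0, **events):
    return CohortStudy(study_id, arm, n, py, events)


class TestPoolRates:
    def test_single_study_closed_form(self):
        """10 events over 1000 person-years: 1%/yr with the Poisson log-rate CI."""
        p = pool_rates([study(late_death=10)], "late_death", "ross")
        assert p.rate == pytest.approx(1.000)
        se = 1 / math.sqrt(10)
        assert p.ci_low == pytest.approx(100 * math.exp(math.log(0.01) - 1.959964 * se), rel=1e-6)
        assert p.ci_high == pytest.approx(100 * math.exp(math.log(0.01) + 1.959964 * se), rel=1e-6)
        assert p.ci_low == pytest.approx(0.538, abs=1e-3)
        assert p.ci_high == pytest.approx(1.858, abs=2e-3)
        assert p.tau2 == 0.0

    def test_duplicated_study_keeps_estimate_and_narrows_ci(self):
        one = pool_rates([study(late_death=10)], "late_death", "ross")
        two = pool_rates(
            [study("a", late_death=10), study("b", late_death=10)], "late_death", "ross"
        )
        assert two.rate == pytest.approx(one.rate)
        assert two.tau2 == 0.0
        assert (two.ci_high - two.ci_low) < (one.ci_high - one.ci_low)

    def test_matches_statsmodels_dersimonian_laird(self):
        """Independent cross-check of the DL machinery on a heterogeneous fixture."""
        from statsmodels.stats.meta_analysis import combine_effects

        studies = [
            study("a", py=800.0, late_death=12),
            study("b", py=2500.0, late_death=60),
            study("c", py=400.0, late_death=3),
            study("d", py=1500.0, late_death=45),
        ]
        ours = pool_rates(studies, "late_death", "ross")
        y = np.log([12 / 800, 60 / 2500, 3 / 400, 45 / 1500])
        v = np.array([1 / 12, 1 / 60, 1 / 3, 1 / 45])
        ref = combine_effects(y, v, method_re="dl")
        assert ours.estimate == pytest.approx(float(ref.mean_effect_re), rel=1e-10)
        assert ours.tau2 == pytest.approx(float(ref.tau2), rel=1e-10)

    def test_zero_event_study_is_continuity_corrected(self):
        p = pool_rates(
            [study("a", late_death=0), study("b", late_death=5)], "late_death", "ross"
        )
        assert p.continuity_corrected

    def test_all_zero_events_warns(self):
        with pytest.warns(UserWarning, match="continuity"):
            pool_rates([study(late_death=0)], "late_death", "ross")

    def test_no_data_raises(self):
        with pytest.raises(NoDataError):
            pool_rates([study(late_death=3)], "bleeding", "ross")

    def test_parameter_recovery_coverage(self):
        """Pooled CI covers the generating rate in >=90% of 200 replicates."""
        hits = 0
        for seed in range(200):
            studies = generate_cohorts(SimulationProfile(seed=seed, n_cohorts_per_arm=20))
            p = pool_rates(studies, "bleeding", "mechAVR")
            hits += p.ci_low <= 0.69 <= p.ci_high
        assert hits / 200 >= 0.90


class TestPoolProportion:
    def test_single_study_identity(self):
        p = pool_proportion([study(n=1000, early_death=3)], "early_death", "ross")
        assert p.rate == pytest.approx(0.30, rel=1e-6)

    def test_equal_underlying_proportion(self):
        studies = [
            study("a", n=800, early_death=2),
            study("b", n=1600, early_death=4),
        ]
        p = pool_proportion(studies, "early_death", "ross")
        assert p.rate == pytest.approx(0.25, rel=1e-6)
        assert p.tau2 == 0.0

    def test_recovery_within_simulation_ci(self):
        hits = 0
        for seed in range(200):
            studies = generate_cohorts(SimulationProfile(seed=seed))
            p = pool_proportion(studies, "early_death", "ross")
            hits += p.ci_low <= 0.24 <= p.ci_high
        assert hits / 200 >= 0.90


class TestCompareArms:
    def test_identical_arms_give_p_one(self):
        pooled = {
            arm: pool_rates([study(arm=arm, late_death=10)], "late_death", arm)
            for arm in ("ross", "mechAVR")
        }
        cmp = compare_arms(pooled, "late_death")
        assert cmp.q_between == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0)

    def test_five_standard_errors_apart_is_significant(self):
        a = pool_rates([study("a", "ross", py=10_000.0, late_death=100)], "late_death", "ross")
        # second arm shifted by 5 pooled SEs on the log scale
        target = math.exp(a.estimate + 5 * math.sqrt(2) * a.se)
        events_b = round(target * 10_000)
        b = pool_rates(
            [study("b", "mechAVR", py=10_000.0, late_death=events_b)], "late_death", "mechAVR"
        )
        assert compare_arms({"ross": a, "mechAVR": b}, "late_death").p_value < 0.001

    def test_power_at_published_mortality_truths(self):
        """Three arms at 0.54/1.38/2.54 %/yr, 15 cohorts each: p < 0.001 nearly always."""
        significant = 0
        for seed in range(100):
            studies = generate_cohorts(SimulationProfile(seed=seed, n_cohorts_per_arm=15))
            pooled = {
                arm: pool_rates(studies, "late_death", arm)
                for arm in ("ross", "mechAVR", "bioAVR")
            }
            significant += compare_arms(pooled, "late_death").p_value < 0.001
        assert significant >= 95

    def test_fewer_than_two_arms_errors(self):
        p = pool_rates([study(late_death=10)], "late_death", "ross")
        with pytest.raises(ValueError):
            compare_arms({"ross": p}, "late_death")


class TestRateToProbability:
    def test_examples(self):
        assert rate_to_probability(0.0, 1.0) == 0.0
        assert rate_to_probability(1.55, 1.0) == pytest.approx(1 - math.exp(-0.0155), rel=1e-12)
        assert rate_to_probability(1.55, 1.0) == pytest.approx(0.015381, abs=1e-6)
        p = rate_to_probability(1000.0, 1.0)
        assert 0.9999 < p < 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.1)

    @given(
        rate=st.floats(min_value=0.0, max_value=50.0),
        delta=st.floats(min_value=0.01, max_value=50.0),
        t=st.floats(min_value=0.1, max_value=2.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_rate_and_time(self, rate, delta, t):
        assert rate_to_probability(rate + delta, t) > rate_to_probability(rate, t)
        assert rate_to_probability(rate + delta, t + 0.5) > rate_to_probability(
            rate + delta, t
        )

    @given(x=st.floats(min_value=1e-6, max_value=0.02))
    @settings(max_examples=50, derandomize=True)
    def test_small_rate_linearisation(self, x):
        """p ~ (rate/100)·t with <1% relative error below rate·t = 0.02."""
        p = rate_to_probability(x * 100.0, 1.0)
        assert abs(p - x) / x < 0.01


class TestTableIO:
    def test_cohort_csv_round_trip(self, tmp_path, cohorts):
        path = tmp_path / "cohorts.csv"
        write_cohort_csv(cohorts, path)
        back = read_cohort_csv(path)
        assert len(back) == len(cohorts)
        assert back[0] == cohorts[0]
        assert {s.arm for s in back} == {"ross", "mechAVR", "bioAVR"}

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("study_id,arm\nx,ross\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_cohort_csv(path)

    def test_pooled_table_shape(self, cohorts):
        table = pooled_table(cohorts)
        assert {"outcome", "unit", "p_value"} <= set(table.columns)
        # RVOT reinterventions exist only after the Ross procedure
        rvot = table[table.outcome == "rvot_reintervention"]
        assert not rvot["ross_rate"].isna().any()
        assert "mechAVR_rate" not in rvot.dropna(axis=1).columns or rvot["mechAVR_rate"].isna().all()
        mortality = table[table.outcome == "late_death"].iloc[0]
        assert mortality.p_value < 0.001
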