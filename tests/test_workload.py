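"""Workload outcomes: daily summaries, unit times, rates, trends, contrasts."""

import datetime as dt

import numpy as np
import pytest

from ccgtam.tam_data import ActivityGroup, TamDataset, VisitOutcome, VisitPurpose
from ccgtam.workload import (
    activity_unit_times,
    bimonthly_trends,
    clinic_time_allocation,
    compare_means,
    compare_medians,
    household_share_pct,
    minutes_per_patient,
    per_day_rates,
    success_rate_pct,
    summarize_days,
    tb_composition,
    visit_outcome_table,
)

from .conftest import make_form


def test_summary_partitions_minutes():
    """10 travel + 15 client-encounter minutes -> field 25, household 15, travel 10."""
    ds = TamDataset(forms=(make_form(),))
    (s,) = summarize_days(ds)
    assert (s.field_minutes, s.household_minutes, s.travel_minutes) == (25, 15, 10)
    assert s.n_attempted == s.n_successful == 1
    assert s.n_patients == 2


def test_empty_dataset_summarizes_to_nothing():
    assert summarize_days(TamDataset(forms=())) == []


def test_household_share_from_period_totals():
    """The published household-time shares follow from the period totals."""
    assert household_share_pct(11_772, 23_786) == pytest.approx(49.5, abs=0.05)
    assert household_share_pct(5_558, 15_881) == pytest.approx(35.0, abs=0.05)


def test_all_travel_day_is_zero_percent_household():
    ds = TamDataset(forms=(make_form(blocks=(("travel", None, 30),), visits=()),))
    alloc = clinic_time_allocation(summarize_days(ds), "clinic1")
    assert alloc.pct_household == 0.0
    assert alloc.pct_travel == 100.0


class TestActivityUnitTimes:
    def test_quartiles_use_linear_interpolation(self):
        """Durations {3,5,8,9}: median 6.5, quartiles by linear interpolation
        between order statistics."""
        blocks = tuple(
            ("health_screening", "v1", d) for d in (3, 5, 8, 9)
        )
        ds = TamDataset(forms=(make_form(blocks=(("travel", None, 5),) + blocks),))
        rows = {r.group: r for r in activity_unit_times(ds, "clinic1") if r.group}
        row = rows[ActivityGroup.CLIENT_ENCOUNTER_OTHER]
        assert row.median == 6.5
        assert (row.q1, row.q3) == (4.5, 8.25)

    def test_single_episode_degenerate_ci(self):
        ds = TamDataset(
            forms=(make_form(blocks=(("travel", None, 5), ("dot_tb", "v1", 7))),)
        )
        rows = {r.group: r for r in activity_unit_times(ds, "clinic1") if r.group}
        row = rows[ActivityGroup.ADHERENCE_SUPPORT_TB]
        assert row.mean == 7 and row.median == 7
        assert row.degenerate_ci and np.isnan(row.ci_low)

    def test_total_row_conserves_minutes(self, small_dataset):
        for clinic in small_dataset.clinic_ids():
            rows = activity_unit_times(small_dataset, clinic)
            total = next(r for r in rows if r.group is None)
            assert total.total_minutes == sum(
                r.total_minutes for r in rows if r.group is not None
            )
            person_minutes = sum(
                f.field_minutes for f in small_dataset.forms_for_clinic(clinic)
            )
            assert total.total_minutes == person_minutes


class TestVisitOutcomes:
    def test_published_success_rates(self):
        assert success_rate_pct(947, 973) == pytest.approx(97.3, abs=0.05)
        assert success_rate_pct(414, 579) == pytest.approx(71.5, abs=0.05)

    def test_outcome_table_counts_and_rates(self):
        visits = [("v1", VisitOutcome.SUCCESS, 1, VisitPurpose.TB_ONLY)]
        visits += [
            (f"v{i}", VisitOutcome.PATIENT_UNAVAILABLE, 0, None) for i in range(2, 5)
        ]
        form = make_form(visits=tuple(visits))
        table = visit_outcome_table(TamDataset(forms=(form,)), "clinic1", 2)
        assert (table.attempted, table.successful, table.failed) == (4, 1, 3)
        assert table.success_rate_pct + table.failure_rate_pct == 100.0
        n, pct, per_month = table.reasons[VisitOutcome.PATIENT_UNAVAILABLE]
        assert (n, pct, per_month) == (3, 75.0, 1.5)
        assert sum(n for n, _, _ in table.reasons.values()) == table.failed

    def test_zero_failures(self):
        table = visit_outcome_table(TamDataset(forms=(make_form(),)), "clinic1", 1)
        assert table.success_rate_pct == 100.0
        assert all(n == 0 for n, _, _ in table.reasons.values())


class TestPerDayRates:
    def test_published_minutes_per_patient(self):
        assert minutes_per_patient(11_772, 1_756) == pytest.approx(6.7, abs=0.05)
        assert minutes_per_patient(5_558, 460) == pytest.approx(12.1, abs=0.05)

    def test_single_day_rates(self):
        form = make_form(
            blocks=(
                ("travel", None, 10),
                ("health_screening", "v1", 10),
                ("health_screening", "v2", 10),
            ),
            visits=(
                ("v1", VisitOutcome.SUCCESS, 2, VisitPurpose.NON_TB_ONLY),
                ("v2", VisitOutcome.SUCCESS, 2, VisitPurpose.BOTH),
            ),
        )
        rates = per_day_rates(summarize_days(TamDataset(forms=(form,))), "clinic1")
        assert rates.households_per_day == 2
        assert rates.patients_per_household == 2
        assert rates.minutes_per_patient == 5.0

    def test_no_patients_flagged_not_thrown(self):
        form = make_form(
            blocks=(("travel", None, 10),),
            visits=(("v1", VisitOutcome.DOOR_LOCKED, 0, None),),
        )
        rates = per_day_rates(summarize_days(TamDataset(forms=(form,))), "clinic1")
        assert np.isnan(rates.minutes_per_patient)


class TestTbComposition:
    def test_single_purpose(self):
        form = make_form()
        comp = tb_composition(TamDataset(forms=(form,)), "clinic1")
        assert (comp.pct_tb_only, comp.pct_non_tb_only, comp.pct_both) == (0, 100, 0)

    def test_mixed_purposes(self):
        visits = (
            ("v1", VisitOutcome.SUCCESS, 1, VisitPurpose.TB_ONLY),
            ("v2", VisitOutcome.SUCCESS, 1, VisitPurpose.BOTH),
            ("v3", VisitOutcome.SUCCESS, 1, VisitPurpose.BOTH),
            ("v4", VisitOutcome.SUCCESS, 1, VisitPurpose.NON_TB_ONLY),
        )
        blocks = (("travel", None, 5),) + tuple(
            ("health_screening", f"v{i}", 5) for i in range(1, 5)
        )
        comp = tb_composition(
            TamDataset(forms=(make_form(blocks=blocks, visits=visits),)), "clinic1"
        )
        assert (comp.pct_tb_only, comp.pct_non_tb_only, comp.pct_both) == (25, 25, 50)
        assert comp.pct_tb_only + comp.pct_non_tb_only + comp.pct_both == 100


class TestBimonthlyTrends:
    def test_adjacent_months_share_a_bin(self):
        forms = (
            make_form(form_id="a", date=dt.date(2018, 3, 10)),
            make_form(form_id="b", date=dt.date(2018, 4, 20)),
        )
        trends = bimonthly_trends(TamDataset(forms=forms))
        assert trends["bin"].nunique() == 1

    def test_march_to_october_gives_four_bins(self):
        forms = tuple(
            make_form(form_id=f"m{m}", date=dt.date(2018, m, 15)) for m in range(3, 11)
        )
        trends = bimonthly_trends(TamDataset(forms=forms))
        assert trends["bin"].nunique() == 4

    def test_stationary_data_shows_no_trend(self, small_dataset):
        """Per-bin travel medians of stationary synthetic data have a slope
        whose CI covers zero."""
        trends = bimonthly_trends(small_dataset)
        travel = trends[(trends["group"] == "travel") & (trends["count"] > 0)]
        slope, intercept = np.polyfit(travel["bin"], travel["median_minutes"], 1)
        resid = travel["median_minutes"] - (slope * travel["bin"] + intercept)
        se = np.sqrt(
            resid.var(ddof=2) / ((travel["bin"] - travel["bin"].mean()) ** 2).sum()
        )
        assert abs(slope) <= 3 * se + 1e-9


class TestCompareMedians:
    def test_shift_recovers_offset(self):
        a = [3.0, 5.0, 8.0, 9.0, 12.0, 4.0]
        b = [x + 5 for x in a]
        res = compare_medians(a, b, n_boot=500, seed=1)
        assert res.estimate == 5.0
        assert res.ci_low <= 5.0 <= res.ci_high

    def test_identical_samples_cover_zero(self):
        a = list(range(1, 30))
        res = compare_medians(a, a, n_boot=500, seed=2)
        assert res.estimate == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_small_bootstrap_rejected(self):
        with pytest.raises(ValueError):
            compare_medians([1, 2], [3, 4], n_boot=50)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        a, b = rng.lognormal(2, 0.5, 50), rng.lognormal(2.5, 0.5, 50)
        r1 = compare_medians(a, b, seed=9)
        r2 = compare_medians(a, b, seed=9)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


class TestCompareMeans:
    def test_estimate_is_mean_difference(self):
        a = [9.0, 10.0, 11.0]
        b = [11.5, 12.8, 14.1]
        res = compare_means(a, b)
        assert res.estimate == pytest.approx(np.mean(b) - np.mean(a))
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_equal_samples_give_zero(self):
        a = [1.0, 2.0, 3.0]
        res = compare_means(a, a)
        assert res.estimate == 0.0

    def test_constant_samples_flagged_degenerate(self):
        res = compare_means([2.0, 2.0, 2.0], [5.0, 5.0])
        assert res.degenerate

    def test_coverage_of_true_difference(self):
        """The Welch-type 95% interval covers a known mean difference ~95% of
        the time under unequal variances."""
        rng = np.random.default_rng(123)
        true_diff, hits, n_sim = 2.0, 0, 1000
        for _ in range(n_sim):
            a = rng.normal(10, 1.0, size=25)
            b = rng.normal(12, 2.5, size=18)
            res = compare_means(a, b)
            hits += res.ci_low <= true_diff <= res.ci_high
        assert 0.93 <= hits / n_sim <= 0.97
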