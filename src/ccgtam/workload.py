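"""Workload analysis of time-and-motion data for CCG outreach teams.

Computes the study's six TAM outcomes per clinic: (1) the length and
travel/household split of a typical field day, (2) unit times per activity
group, (3) per-day visit and patient rates, (4) frequency and reasons for
unsuccessful visit attempts, (5) bi-monthly trends in activity frequency and
duration, and (6) the TB-care composition of household visits — plus the two
between-clinic comparison contracts (difference in medians with a bootstrap
CI, and difference in means with a Welch-type robust CI).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tam_data import (
    ActivityGroup,
    DailyForm,
    FAILURE_REASONS,
    TamDataset,
    VisitOutcome,
    VisitPurpose,
)

__all__ = [
    "DailySummary",
    "TimeAllocation",
    "ActivitySummaryRow",
    "DayRates",
    "OutcomeTable",
    "TbComposition",
    "ComparisonResult",
    "summarize_days",
    "clinic_time_allocation",
    "activity_unit_times",
    "visit_outcome_table",
    "per_day_rates",
    "tb_composition",
    "bimonthly_trends",
    "compare_medians",
    "compare_means",
    "household_share_pct",
    "success_rate_pct",
    "minutes_per_patient",
]


# ---------------------------------------------------------------------------
# scalar helpers (the arithmetic behind the derived table cells)

def household_share_pct(household_minutes: float, field_minutes: float) -> float:
    """Percent of observed field time spent at households (vs traveling)."""
    if field_minutes <= 0:
        raise ValueError("field_minutes must be positive")
    return 100.0 * household_minutes / field_minutes


def success_rate_pct(successful: int, attempted: int) -> float:
    if attempted <= 0:
        raise ValueError("attempted must be positive")
    return 100.0 * successful / attempted


def minutes_per_patient(household_minutes: float, n_patients: int) -> float:
    """Mean direct person-time per patient seen; NaN when no patients."""
    if n_patients <= 0:
        return float("nan")
    return household_minutes / n_patients


# ---------------------------------------------------------------------------
# outcome 1: the field day

@dataclass(frozen=True)
class DailySummary:
    """One CCG-pair field day reduced to its workload measures."""

    daily_form_id: str
    pair_id: str
    clinic_id: str
    date: dt.date
    field_minutes: int
    household_minutes: int
    travel_minutes: int
    n_attempted: int
    n_successful: int
    n_patients: int


def summarize_days(dataset: TamDataset) -> list[DailySummary]:
    """One summary row per (quality-filtered) daily form.

    Person-minutes partition into household (direct activities) and travel
    (indirect) by activity group.
    """
    out = []
    for f in dataset.forms:
        travel = sum(r.duration for r in f.records if not r.is_direct)
        household = sum(r.duration for r in f.records if r.is_direct)
        out.append(
            DailySummary(
                daily_form_id=f.daily_form_id,
                pair_id=f.pair_id,
                clinic_id=f.clinic_id,
                date=f.date,
                field_minutes=f.field_minutes,
                household_minutes=household,
                travel_minutes=travel,
                n_attempted=len(f.visits),
                n_successful=sum(1 for v in f.visits if v.successful),
                n_patients=sum(v.n_patients for v in f.visits),
            )
        )
    return out


@dataclass(frozen=True)
class TimeAllocation:
    clinic_id: str
    pct_household: float
    pct_travel: float
    pct_household_range: tuple[float, float]  # (min, max) over pairs


def clinic_time_allocation(
    summaries: Sequence[DailySummary], clinic_id: str
) -> TimeAllocation:
    """Clinic-level household/travel split of field time, with per-pair range."""
    rows = [s for s in summaries if s.clinic_id == clinic_id]
    if not rows:
        raise ValueError(f"no summaries for clinic {clinic_id!r}")
    pct = household_share_pct(
        sum(s.household_minutes for s in rows), sum(s.field_minutes for s in rows)
    )
    per_pair = {}
    for s in rows:
        h, f = per_pair.get(s.pair_id, (0, 0))
        per_pair[s.pair_id] = (h + s.household_minutes, f + s.field_minutes)
    pair_pcts = [household_share_pct(h, f) for h, f in per_pair.values() if f > 0]
    return TimeAllocation(
        clinic_id=clinic_id,
        pct_household=pct,
        pct_travel=100.0 - pct,
        pct_household_range=(min(pair_pcts), max(pair_pcts)),
    )


# ---------------------------------------------------------------------------
# outcome 2: unit times per activity group

@dataclass(frozen=True)
class ActivitySummaryRow:
    group: ActivityGroup | None  # None for the Total row
    count: int
    pct_count: float
    total_minutes: int
    pct_minutes: float
    mean: float
    ci_low: float
    ci_high: float
    median: float
    q1: float
    q3: float
    degenerate_ci: bool = False


def _mean_ci(durations: np.ndarray) -> tuple[float, float, float, bool]:
    """t-based 95% CI for the mean; degenerate below 2 observations."""
    mean = float(durations.mean())
    n = durations.size
    if n < 2:
        return mean, float("nan"), float("nan"), True
    se = float(durations.std(ddof=1)) / math.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    return mean, mean - tcrit * se, mean + tcrit * se, False


def _quartiles(durations: np.ndarray) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation between order statistics."""
    q1, med, q3 = np.percentile(durations, [25, 50, 75])
    return float(med), float(q1), float(q3)


def activity_unit_times(
    dataset: TamDataset, clinic_id: str
) -> list[ActivitySummaryRow]:
    """Per-group episode counts, person-minutes and duration statistics.

    Returns one row per activity group in fixed order plus a Total row
    (group=None).  Percentages are of the clinic's total episode count and
    total person-minutes respectively.
    """
    durations: dict[ActivityGroup, list[int]] = {g: [] for g in ActivityGroup}
    for f in dataset.forms_for_clinic(clinic_id):
        for r in f.records:
            durations[r.group].append(r.duration)
    total_count = sum(len(v) for v in durations.values())
    total_minutes = sum(sum(v) for v in durations.values())

    rows = []
    for g in ActivityGroup:
        ds = np.asarray(durations[g], dtype=float)
        if ds.size == 0:
            rows.append(
                ActivitySummaryRow(
                    group=g, count=0, pct_count=0.0, total_minutes=0, pct_minutes=0.0,
                    mean=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                    median=float("nan"), q1=float("nan"), q3=float("nan"),
                    degenerate_ci=True,
                )
            )
            continue
        mean, lo, hi, degenerate = _mean_ci(ds)
        med, q1, q3 = _quartiles(ds)
        rows.append(
            ActivitySummaryRow(
                group=g,
                count=int(ds.size),
                pct_count=100.0 * ds.size / total_count if total_count else 0.0,
                total_minutes=int(ds.sum()),
                pct_minutes=100.0 * ds.sum() / total_minutes if total_minutes else 0.0,
                mean=mean,
                ci_low=lo,
                ci_high=hi,
                median=med,
                q1=q1,
                q3=q3,
                degenerate_ci=degenerate,
            )
        )
    rows.append(
        ActivitySummaryRow(
            group=None,
            count=total_count,
            pct_count=100.0 if total_count else 0.0,
            total_minutes=total_minutes,
            pct_minutes=100.0 if total_minutes else 0.0,
            mean=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            median=float("nan"), q1=float("nan"), q3=float("nan"),
            degenerate_ci=True,
        )
    )
    return rows


# ---------------------------------------------------------------------------
# outcome 4: unsuccessful visit attempts

@dataclass(frozen=True)
class OutcomeTable:
    clinic_id: str
    attempted: int
    successful: int
    failed: int
    success_rate_pct: float
    failure_rate_pct: float
    reasons: Mapping[VisitOutcome, tuple[int, float, float]]  # count, %, per month


def visit_outcome_table(
    dataset: TamDataset, clinic_id: str, months_observed: int
) -> OutcomeTable:
    """Counts and reasons of unsuccessful visits, as shares of all attempts."""
    if months_observed < 1:
        raise ValueError("months_observed must be >= 1")
    visits = [v for f in dataset.forms_for_clinic(clinic_id) for v in f.visits]
    attempted = len(visits)
    if attempted == 0:
        raise ValueError(f"no visit attempts for clinic {clinic_id!r}")
    successful = sum(1 for v in visits if v.successful)
    failed = attempted - successful
    reasons = {}
    for reason in FAILURE_REASONS:
        n = sum(1 for v in visits if v.outcome is reason)
        reasons[reason] = (n, 100.0 * n / attempted, n / months_observed)
    return OutcomeTable(
        clinic_id=clinic_id,
        attempted=attempted,
        successful=successful,
        failed=failed,
        success_rate_pct=success_rate_pct(successful, attempted),
        failure_rate_pct=100.0 * failed / attempted,
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# outcome 3: per-day rates

@dataclass(frozen=True)
class DayRates:
    clinic_id: str
    households_per_day: float  # mean successful visits over days
    patients_per_day: float
    patients_per_household: float
    minutes_per_patient: float  # NaN if no patients observed


def per_day_rates(summaries: Sequence[DailySummary], clinic_id: str) -> DayRates:
    """Visit and patient rates for one clinic.

    Per-day rates are means of the per-day counts; per-patient time and
    patients-per-household are ratios of period totals.
    """
    rows = [s for s in summaries if s.clinic_id == clinic_id]
    if not rows:
        raise ValueError(f"no summaries for clinic {clinic_id!r}")
    total_patients = sum(s.n_patients for s in rows)
    total_successful = sum(s.n_successful for s in rows)
    return DayRates(
        clinic_id=clinic_id,
        households_per_day=float(np.mean([s.n_successful for s in rows])),
        patients_per_day=float(np.mean([s.n_patients for s in rows])),
        patients_per_household=(
            total_patients / total_successful if total_successful else float("nan")
        ),
        minutes_per_patient=minutes_per_patient(
            sum(s.household_minutes for s in rows), total_patients
        ),
    )


# ---------------------------------------------------------------------------
# outcome 6: TB composition of successful visits

@dataclass(frozen=True)
class TbComposition:
    clinic_id: str
    pct_tb_only: float
    pct_non_tb_only: float
    pct_both: float
    ranges: Mapping[VisitPurpose, tuple[float, float]]  # (min, max) over pairs


def tb_composition(dataset: TamDataset, clinic_id: str) -> TbComposition:
    """Share of successful visits that were TB-only, non-TB-only, or both."""
    by_pair: dict[str, list[VisitPurpose]] = {}
    purposes: list[VisitPurpose] = []
    for f in dataset.forms_for_clinic(clinic_id):
        for v in f.visits:
            if v.successful and v.purpose is not None:
                purposes.append(v.purpose)
                by_pair.setdefault(f.pair_id, []).append(v.purpose)
    if not purposes:
        raise ValueError(f"no successful visits for clinic {clinic_id!r}")

    def share(ps: Sequence[VisitPurpose], which: VisitPurpose) -> float:
        return 100.0 * sum(1 for p in ps if p is which) / len(ps)

    ranges = {}
    for which in VisitPurpose:
        pair_shares = [share(ps, which) for ps in by_pair.values()]
        ranges[which] = (min(pair_shares), max(pair_shares))
    return TbComposition(
        clinic_id=clinic_id,
        pct_tb_only=share(purposes, VisitPurpose.TB_ONLY),
        pct_non_tb_only=share(purposes, VisitPurpose.NON_TB_ONLY),
        pct_both=share(purposes, VisitPurpose.BOTH),
        ranges=ranges,
    )


# ---------------------------------------------------------------------------
# outcome 5: bi-monthly trends

def bimonthly_trends(dataset: TamDataset) -> pd.DataFrame:
    """Episode counts and median durations in consecutive 2-calendar-month bins.

    Bins start at the month of the earliest form; empty (bin, group) cells
    are reported with zero count and NaN median.
    """
    if not dataset.forms:
        raise ValueError("dataset is empty")
    months = [f.date.year * 12 + (f.date.month - 1) for f in dataset.forms]
    start = min(months)
    n_bins = (max(months) - start) // 2 + 1

    durations: dict[tuple[int, ActivityGroup], list[int]] = {}
    for f in dataset.forms:
        b = (f.date.year * 12 + (f.date.month - 1) - start) // 2
        for r in f.records:
            durations.setdefault((b, r.group), []).append(r.duration)

    rows = []
    for b in range(n_bins):
        y, m = divmod(start + 2 * b, 12)
        for g in ActivityGroup:
            ds = durations.get((b, g), [])
            rows.append(
                {
                    "bin": b,
                    "bin_start": dt.date(y, m + 1, 1),
                    "group": g.value,
                    "count": len(ds),
                    "median_minutes": float(np.median(ds)) if ds else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# between-clinic comparisons

@dataclass(frozen=True)
class ComparisonResult:
    """Clinic-2-minus-clinic-1 style contrast with a 95% interval."""

    estimate: float
    ci_low: float
    ci_high: float
    method: str  # "median_bootstrap" or "mean_robust"
    degenerate: bool = False


def compare_medians(
    sample_a: Iterable[float],
    sample_b: Iterable[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> ComparisonResult:
    """Difference in medians (b − a) with a seeded percentile-bootstrap 95% CI.

    A distribution-free stand-in for quantile regression on a group
    indicator: the point estimate is identical; the interval is resampled.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    estimate = float(np.median(b) - np.median(a))
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = np.median(b[ib], axis=1) - np.median(a[ia], axis=1)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return ComparisonResult(
        estimate=estimate,
        ci_low=min(float(lo), estimate),
        ci_high=max(float(hi), estimate),
        method="median_bootstrap",
    )


def compare_means(
    sample_a: Iterable[float], sample_b: Iterable[float]
) -> ComparisonResult:
    """Difference in means (b − a) with an unequal-variance (Welch) 95% CI.

    Equivalent to the heteroskedasticity-robust standard error of a group
    indicator in a two-group linear regression.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 elements")
    estimate = float(b.mean() - a.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return ComparisonResult(
            estimate=estimate, ci_low=estimate, ci_high=estimate,
            method="mean_robust", degenerate=True,
        )
    se = math.sqrt(va / a.size + vb / b.size)
    df = (va / a.size + vb / b.size) ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    tcrit = stats.t.ppf(0.975, df)
    return ComparisonResult(
        estimate=estimate,
        ci_low=estimate - tcrit * se,
        ci_high=estimate + tcrit * se,
        method="mean_robust",
    )
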