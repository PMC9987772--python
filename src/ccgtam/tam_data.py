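"""Domain types, delimited-text I/O, and quality validation for time-and-motion (TAM) data.

A TAM dataset records the field work of community caregiver (CCG) pairs:
each *daily form* covers one pair-day (depart/return clock times), and is
linked to the *household visits* attempted that day and the timed, coded
*activity records* that fill the day contiguously — activities are logged
back-to-back with no time gaps, so the sum of activity durations equals the
time spent in the field.

Times are stored as whole minutes since midnight (reporting resolution is
one minute); dates are ISO-8601 calendar dates.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ActivityGroup",
    "ACTIVITY_CODES",
    "VisitOutcome",
    "VisitPurpose",
    "QualityIssue",
    "ActivityRecord",
    "HouseholdVisit",
    "DailyForm",
    "ClinicProfile",
    "QualityVerdict",
    "TamDataset",
    "TamLinkageError",
    "UnknownActivityCodeError",
    "read_tam_dataset",
    "write_tam_dataset",
    "read_clinic_profiles",
    "write_clinic_profiles",
    "validate_daily_form",
    "apply_quality_filter",
    "minutes_to_hhmm",
    "hhmm_to_minutes",
]


class ActivityGroup(str, enum.Enum):
    """The six activity groups used to classify CCG field work.

    Five groups are *direct* (service provision at a household); travel
    between the clinic and households is the only *indirect* group.
    """

    ADHERENCE_SUPPORT_TB = "adherence_support_tb"
    ADHERENCE_SUPPORT_OTHER = "adherence_support_other"
    CLIENT_ENCOUNTER_TB = "client_encounter_tb"
    CLIENT_ENCOUNTER_OTHER = "client_encounter_other"
    HOME_BASED_CARE = "home_based_care"
    TRAVEL = "travel"

    @property
    def is_direct(self) -> bool:
        return self is not ActivityGroup.TRAVEL


#: Recognized activity codes and the group each maps to.  The group labels
#: themselves are valid codes; the named codes cover the common field
#: activities (DOT = directly observed treatment).
ACTIVITY_CODES: dict[str, ActivityGroup] = {
    **{g.value: g for g in ActivityGroup},
    "dot_tb": ActivityGroup.ADHERENCE_SUPPORT_TB,
    "adherence_counselling_tb": ActivityGroup.ADHERENCE_SUPPORT_TB,
    "medicine_delivery": ActivityGroup.ADHERENCE_SUPPORT_OTHER,
    "adherence_counselling_other": ActivityGroup.ADHERENCE_SUPPORT_OTHER,
    "symptom_screening_tb": ActivityGroup.CLIENT_ENCOUNTER_TB,
    "sputum_collection": ActivityGroup.CLIENT_ENCOUNTER_TB,
    "contact_tracing_tb": ActivityGroup.CLIENT_ENCOUNTER_TB,
    "health_screening": ActivityGroup.CLIENT_ENCOUNTER_OTHER,
    "health_counselling": ActivityGroup.CLIENT_ENCOUNTER_OTHER,
    "household_registration": ActivityGroup.CLIENT_ENCOUNTER_OTHER,
    "meal_assistance": ActivityGroup.HOME_BASED_CARE,
    "bathing_assistance": ActivityGroup.HOME_BASED_CARE,
    "travel_between_households": ActivityGroup.TRAVEL,
    "travel_clinic_household": ActivityGroup.TRAVEL,
}


class VisitOutcome(str, enum.Enum):
    SUCCESS = "success"
    PATIENT_UNAVAILABLE = "patient_unavailable"
    WRONG_ADDRESS = "wrong_address"
    DECEASED = "deceased"
    RELOCATED = "relocated"
    DOOR_LOCKED = "door_locked"
    REFUSED_CARE = "refused_care"
    UNKNOWN_PATIENT = "unknown_patient"


#: Failure reasons in fixed reporting order.
FAILURE_REASONS: tuple[VisitOutcome, ...] = tuple(
    o for o in VisitOutcome if o is not VisitOutcome.SUCCESS
)


class VisitPurpose(str, enum.Enum):
    TB_ONLY = "tb_only"
    NON_TB_ONLY = "non_tb_only"
    BOTH = "both"


class QualityIssue(str, enum.Enum):
    TIME_GAP = "time_gap"
    MISSING_FIELD = "missing_field"
    UNIFORM_DURATIONS = "uniform_durations"
    NON_CONTIGUOUS = "non_contiguous"
    OTHER = "other"


def hhmm_to_minutes(text: str) -> int:
    """Parse a 24-h ``HH:MM`` clock time into minutes since midnight."""
    hh, mm = text.strip().split(":")
    h, m = int(hh), int(mm)
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"invalid clock time {text!r}")
    return 60 * h + m


def minutes_to_hhmm(minutes: int) -> str:
    if not 0 <= minutes < 24 * 60:
        raise ValueError(f"minutes-since-midnight out of range: {minutes}")
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


@dataclass(frozen=True)
class ActivityRecord:
    """One timed, coded activity performed by a CCG pair.

    ``start`` and ``end`` are minutes since midnight; non-travel records link
    to the household visit they served via ``visit_id``.
    """

    record_id: str
    daily_form_id: str
    code: str
    start: int
    end: int
    visit_id: str | None = None

    @property
    def group(self) -> ActivityGroup:
        return ACTIVITY_CODES[self.code]

    @property
    def is_direct(self) -> bool:
        return self.group.is_direct

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HouseholdVisit:
    """One household visit attempt.

    A *successful* visit is one where the pair interacted with at least one
    patient; otherwise the outcome records the failure reason and no direct
    activity time is attributed to the household.
    """

    visit_id: str
    daily_form_id: str
    outcome: VisitOutcome
    n_patients: int
    purpose: VisitPurpose | None

    @property
    def successful(self) -> bool:
        return self.outcome is VisitOutcome.SUCCESS


@dataclass(frozen=True)
class DailyForm:
    """One CCG-pair field day, with its linked visits and activity records."""

    daily_form_id: str
    pair_id: str
    clinic_id: str
    date: dt.date
    depart: int
    return_time: int
    visits: tuple[HouseholdVisit, ...] = ()
    records: tuple[ActivityRecord, ...] = ()

    @property
    def field_minutes(self) -> int:
        return self.return_time - self.depart

    def sorted_records(self) -> tuple[ActivityRecord, ...]:
        return tuple(sorted(self.records, key=lambda r: (r.start, r.end)))


@dataclass(frozen=True)
class ClinicProfile:
    clinic_id: str
    setting: str
    catchment_km2: float
    households_registered: int
    n_pairs: int
    n_team_members: int
    n_supervisors: int

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.households_registered < 1:
            raise ValueError("households_registered must be >= 1")


@dataclass(frozen=True)
class QualityVerdict:
    daily_form_id: str
    reasons: tuple[QualityIssue, ...]

    @property
    def included(self) -> bool:
        return not self.reasons


@dataclass(frozen=True)
class TamDataset:
    """A collection of daily forms, optionally with clinic profiles."""

    forms: tuple[DailyForm, ...]
    clinics: tuple[ClinicProfile, ...] = ()

    def __len__(self) -> int:
        return len(self.forms)

    def clinic_ids(self) -> tuple[str, ...]:
        return tuple(sorted({f.clinic_id for f in self.forms}))

    def forms_for_clinic(self, clinic_id: str) -> tuple[DailyForm, ...]:
        return tuple(f for f in self.forms if f.clinic_id == clinic_id)

    def clinic_profile(self, clinic_id: str) -> ClinicProfile:
        for c in self.clinics:
            if c.clinic_id == clinic_id:
                return c
        raise KeyError(f"no profile for clinic {clinic_id!r}")

    def all_visits(self) -> tuple[HouseholdVisit, ...]:
        return tuple(v for f in self.forms for v in f.visits)

    def all_records(self) -> tuple[ActivityRecord, ...]:
        return tuple(r for f in self.forms for r in f.records)


class TamLinkageError(ValueError):
    """Raised when rows reference identifiers that do not exist."""

    def __init__(self, message: str, offending_ids: Sequence[str]):
        super().__init__(f"{message}: {', '.join(sorted(offending_ids))}")
        self.offending_ids = tuple(sorted(offending_ids))


class UnknownActivityCodeError(ValueError):
    pass


DAILY_COLUMNS = ["daily_form_id", "pair_id", "clinic_id", "date", "depart", "return"]
VISIT_COLUMNS = ["visit_id", "daily_form_id", "outcome", "n_patients", "purpose"]
ACTIVITY_COLUMNS = ["record_id", "daily_form_id", "visit_id", "code", "start", "end"]
CLINIC_COLUMNS = [
    "clinic_id",
    "setting",
    "catchment_km2",
    "households_registered",
    "n_pairs",
    "n_team_members",
    "n_supervisors",
]


def _read_table(path: Path | str, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_tam_dataset(
    daily_path: Path | str,
    activity_path: Path | str,
    visit_path: Path | str,
    clinic_path: Path | str | None = None,
) -> TamDataset:
    """Read the three linked CSV tables into a :class:`TamDataset`.

    Raises :class:`TamLinkageError` naming the offending identifiers if any
    visit or activity row references a daily form (or visit) that does not
    exist, and :class:`UnknownActivityCodeError` for unrecognized codes.
    """
    daily = _read_table(daily_path, DAILY_COLUMNS)
    daily = daily.rename(columns={"return": "return_time"})
    visits = _read_table(visit_path, VISIT_COLUMNS)
    acts = _read_table(activity_path, ACTIVITY_COLUMNS)

    form_ids = set(daily["daily_form_id"])
    bad_visit_links = [
        v for v, f in zip(visits["visit_id"], visits["daily_form_id"]) if f not in form_ids
    ]
    if bad_visit_links:
        raise TamLinkageError(
            "visit rows reference unknown daily forms", bad_visit_links
        )
    visit_ids = set(visits["visit_id"])
    bad_act_form = [
        r for r, f in zip(acts["record_id"], acts["daily_form_id"]) if f not in form_ids
    ]
    if bad_act_form:
        raise TamLinkageError(
            "activity rows reference unknown daily forms", bad_act_form
        )
    bad_act_visit = [
        r
        for r, v in zip(acts["record_id"], acts["visit_id"])
        if v != "" and v not in visit_ids
    ]
    if bad_act_visit:
        raise TamLinkageError(
            "activity rows reference unknown visits", bad_act_visit
        )
    unknown_codes = sorted(set(acts["code"]) - set(ACTIVITY_CODES))
    if unknown_codes:
        raise UnknownActivityCodeError(f"unknown activity codes: {unknown_codes}")

    visits_by_form: dict[str, list[HouseholdVisit]] = {}
    for row in visits.itertuples(index=False):
        visits_by_form.setdefault(row.daily_form_id, []).append(
            HouseholdVisit(
                visit_id=row.visit_id,
                daily_form_id=row.daily_form_id,
                outcome=VisitOutcome(row.outcome),
                n_patients=int(row.n_patients),
                purpose=VisitPurpose(row.purpose) if row.purpose else None,
            )
        )
    acts_by_form: dict[str, list[ActivityRecord]] = {}
    for row in acts.itertuples(index=False):
        acts_by_form.setdefault(row.daily_form_id, []).append(
            ActivityRecord(
                record_id=row.record_id,
                daily_form_id=row.daily_form_id,
                code=row.code,
                start=hhmm_to_minutes(row.start),
                end=hhmm_to_minutes(row.end),
                visit_id=row.visit_id or None,
            )
        )

    forms = []
    for row in daily.itertuples(index=False):
        forms.append(
            DailyForm(
                daily_form_id=row.daily_form_id,
                pair_id=row.pair_id,
                clinic_id=row.clinic_id,
                date=dt.date.fromisoformat(row.date),
                depart=hhmm_to_minutes(row.depart),
                return_time=hhmm_to_minutes(row.return_time),
                visits=tuple(visits_by_form.get(row.daily_form_id, ())),
                records=tuple(
                    sorted(
                        acts_by_form.get(row.daily_form_id, ()),
                        key=lambda r: (r.start, r.end),
                    )
                ),
            )
        )
    forms.sort(key=lambda f: (f.pair_id, f.date, f.daily_form_id))

    clinics: tuple[ClinicProfile, ...] = ()
    if clinic_path is not None:
        clinics = read_clinic_profiles(clinic_path)
    return TamDataset(forms=tuple(forms), clinics=clinics)


def write_tam_dataset(dataset: TamDataset, out_dir: Path | str) -> dict[str, Path]:
    """Write ``daily.csv``, ``visits.csv`` and ``activities.csv`` to *out_dir*.

    Rows are ordered deterministically by (pair_id, date, start) so identical
    datasets serialize byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    forms = sorted(dataset.forms, key=lambda f: (f.pair_id, f.date, f.daily_form_id))

    daily_rows, visit_rows, act_rows = [], [], []
    for f in forms:
        daily_rows.append(
            {
                "daily_form_id": f.daily_form_id,
                "pair_id": f.pair_id,
                "clinic_id": f.clinic_id,
                "date": f.date.isoformat(),
                "depart": minutes_to_hhmm(f.depart),
                "return": minutes_to_hhmm(f.return_time),
            }
        )
        for v in f.visits:
            visit_rows.append(
                {
                    "visit_id": v.visit_id,
                    "daily_form_id": v.daily_form_id,
                    "outcome": v.outcome.value,
                    "n_patients": v.n_patients,
                    "purpose": v.purpose.value if v.purpose else "",
                }
            )
        for r in f.sorted_records():
            act_rows.append(
                {
                    "record_id": r.record_id,
                    "daily_form_id": r.daily_form_id,
                    "visit_id": r.visit_id or "",
                    "code": r.code,
                    "start": minutes_to_hhmm(r.start),
                    "end": minutes_to_hhmm(r.end),
                }
            )

    paths = {
        "daily": out / "daily.csv",
        "visits": out / "visits.csv",
        "activities": out / "activities.csv",
    }
    pd.DataFrame(daily_rows, columns=DAILY_COLUMNS).to_csv(paths["daily"], index=False)
    pd.DataFrame(visit_rows, columns=VISIT_COLUMNS).to_csv(paths["visits"], index=False)
    pd.DataFrame(act_rows, columns=ACTIVITY_COLUMNS).to_csv(
        paths["activities"], index=False
    )
    if dataset.clinics:
        paths["clinics"] = out / "clinics.csv"
        write_clinic_profiles(dataset.clinics, paths["clinics"])
    return paths


def read_clinic_profiles(path: Path | str) -> tuple[ClinicProfile, ...]:
    df = _read_table(path, CLINIC_COLUMNS)
    return tuple(
        ClinicProfile(
            clinic_id=row.clinic_id,
            setting=row.setting,
            catchment_km2=float(row.catchment_km2),
            households_registered=int(row.households_registered),
            n_pairs=int(row.n_pairs),
            n_team_members=int(row.n_team_members),
            n_supervisors=int(row.n_supervisors),
        )
        for row in df.itertuples(index=False)
    )


def write_clinic_profiles(clinics: Iterable[ClinicProfile], path: Path | str) -> Path:
    rows = [
        {
            "clinic_id": c.clinic_id,
            "setting": c.setting,
            "catchment_km2": c.catchment_km2,
            "households_registered": c.households_registered,
            "n_pairs": c.n_pairs,
            "n_team_members": c.n_team_members,
            "n_supervisors": c.n_supervisors,
        }
        for c in sorted(clinics, key=lambda c: c.clinic_id)
    ]
    pd.DataFrame(rows, columns=CLINIC_COLUMNS).to_csv(path, index=False)
    return Path(path)


# Minimum record count before an all-equal-durations pattern is treated as
# suspicious rather than a legitimately short day.
UNIFORM_DURATION_MIN_RECORDS = 3


def validate_daily_form(form: DailyForm) -> QualityVerdict:
    """Apply the TAM quality rules to one daily form.

    Rules, mirroring the field-data validation protocol: activities must be
    recorded continuously and consecutively (first start = depart, each start
    = previous end, last end = return to clinic) with no time gaps or
    overlaps; required fields must be present; and a form whose activities
    all last exactly the same duration (with >= 3 of them) is flagged as a
    suspicious reporting pattern.  Returns a verdict, never raises.
    """
    reasons: list[QualityIssue] = []

    if not form.records:
        reasons.append(QualityIssue.MISSING_FIELD)
    if any(
        v.outcome is VisitOutcome.SUCCESS and v.purpose is None for v in form.visits
    ):
        reasons.append(QualityIssue.MISSING_FIELD)

    if form.return_time <= form.depart:
        # covers overnight forms (return before depart), which are rejected
        reasons.append(QualityIssue.NON_CONTIGUOUS)

    recs = form.sorted_records()
    if recs:
        if any(r.duration < 1 for r in recs):
            reasons.append(QualityIssue.NON_CONTIGUOUS)
        cursor = form.depart
        gap = overlap = False
        for r in recs:
            if r.start > cursor:
                gap = True
            elif r.start < cursor:
                overlap = True
            cursor = max(cursor, r.end)
        if recs[-1].end < form.return_time:
            gap = True
        if recs[-1].end > form.return_time:
            overlap = True
        if gap:
            reasons.append(QualityIssue.TIME_GAP)
        if overlap:
            reasons.append(QualityIssue.NON_CONTIGUOUS)

        durations = [r.duration for r in recs]
        if len(durations) >= UNIFORM_DURATION_MIN_RECORDS and len(set(durations)) == 1:
            reasons.append(QualityIssue.UNIFORM_DURATIONS)

    # linkage sanity: travel must not be attributed to a household; direct
    # activity must be; failed visits must not accrue direct time or patients
    linked_visits = {v.visit_id: v for v in form.visits}
    for r in recs:
        if r.group is ActivityGroup.TRAVEL and r.visit_id is not None:
            reasons.append(QualityIssue.OTHER)
            break
        if r.group.is_direct and r.visit_id is None:
            reasons.append(QualityIssue.OTHER)
            break
        if r.visit_id is not None and r.visit_id in linked_visits:
            if not linked_visits[r.visit_id].successful:
                reasons.append(QualityIssue.OTHER)
                break
    for v in form.visits:
        if v.successful and v.n_patients < 1:
            reasons.append(QualityIssue.OTHER)
            break
        if not v.successful and v.n_patients != 0:
            reasons.append(QualityIssue.OTHER)
            break

    # deduplicate, preserving order
    seen: dict[QualityIssue, None] = dict.fromkeys(reasons)
    return QualityVerdict(daily_form_id=form.daily_form_id, reasons=tuple(seen))


def apply_quality_filter(
    dataset: TamDataset,
) -> tuple[TamDataset, tuple[QualityVerdict, ...]]:
    """Drop poor-quality forms; return the retained dataset and exclusion log.

    Retained + excluded always partition the input: the log holds one verdict
    per excluded form.
    """
    retained: list[DailyForm] = []
    excluded: list[QualityVerdict] = []
    for form in dataset.forms:
        verdict = validate_daily_form(form)
        if verdict.included:
            retained.append(form)
        else:
            excluded.append(verdict)
    return TamDataset(forms=tuple(retained), clinics=dataset.clinics), tuple(excluded)
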