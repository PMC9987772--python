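"""Seeded synthetic TAM datasets and cost registers.

The generator emulates the structure of the two-clinic CCG field study so
every downstream stage (validation, workload analysis, costing) can be
exercised and calibration-checked without the study's raw forms.  Each
pair-day alternates travel and household-visit blocks until a drawn daily
field-time target is reached; visit attempts succeed with a per-clinic
probability, successful visits accrue patients, a care purpose and 1-3 timed
direct activities, and failures occupy only their travel episode (the brief
doorstep interval is absorbed into it).  Durations are log-normal,
parameterized by matching published medians and interquartile ranges.

Identical (configs, seed) inputs produce byte-identical datasets.
"""

from __future__ import annotations

import datetime as dt
import math
from decimal import Decimal
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import reference as ref
from .costing import CostCategory, CostItem, SHARED
from .tam_data import (
    ActivityGroup,
    ActivityRecord,
    ClinicProfile,
    DailyForm,
    FAILURE_REASONS,
    HouseholdVisit,
    TamDataset,
    VisitOutcome,
    VisitPurpose,
)

__all__ = [
    "DistSpec",
    "TruncatedPoissonSpec",
    "ClinicGeneratorConfig",
    "default_clinic_configs",
    "generate_dataset",
    "generate_cost_register",
    "default_cost_register",
    "configs_to_yaml",
    "configs_from_yaml",
]

# standard normal quartile: q25/q75 of a lognormal sit at exp(mu -/+ 0.6745 sigma)
_Z75 = 1.3489795003921634 / 2


class DistSpec(BaseModel):
    """A positive, right-skewed duration distribution given as median + IQR.

    Sampled as log-normal with ``mu = ln(median)`` and ``sigma`` chosen so the
    theoretical quartile ratio matches ``q3/q1``.  ``q1 == q3`` degenerates to
    a constant.
    """

    model_config = ConfigDict(frozen=True)

    median: float = Field(gt=0)
    q1: float = Field(gt=0)
    q3: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "DistSpec":
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("require q1 <= median <= q3")
        return self

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return math.log(self.q3 / self.q1) / (2 * _Z75)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.lognormal(self.mu, self.sigma, size=size)

    def sample_minutes(self, rng: np.random.Generator) -> int:
        """One draw rounded to whole minutes, at least 1."""
        return max(1, round(float(self.sample(rng))))

    @property
    def mean(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2)


class TruncatedPoissonSpec(BaseModel):
    """Patients per successfully visited household: 1 + Poisson(lam), capped."""

    model_config = ConfigDict(frozen=True)

    lam: float = Field(ge=0)
    max_patients: int = Field(default=5, ge=1)

    def sample(self, rng: np.random.Generator) -> int:
        return 1 + min(int(rng.poisson(self.lam)), self.max_patients - 1)


def _simplex(weights: Mapping, what: str) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} must sum to 1 (got {total!r})")
    if any(w < 0 for w in weights.values()):
        raise ValueError(f"{what} must be non-negative")


class ClinicGeneratorConfig(BaseModel):
    """All parameters governing synthetic TAM data for one clinic."""

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    clinic_profile: ClinicProfile
    days_per_pair: int = Field(ge=1)
    daily_field_minutes: DistSpec
    field_minutes_clip: tuple[int, int] = (100, 350)
    travel_minutes: DistSpec
    visit_minutes_by_group: dict[ActivityGroup, DistSpec]
    p_success: float = Field(ge=0, le=1)
    failure_reason_weights: dict[VisitOutcome, float]
    patients_per_household: TruncatedPoissonSpec
    purpose_weights: dict[VisitPurpose, float]
    activity_group_weights: dict[ActivityGroup, float]
    activities_per_visit_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    doorstep_minutes: int = Field(default=2, ge=0)
    p_corrupt_form: float = Field(ge=0, le=1, default=0.0)
    start_date: dt.date = dt.date.fromisoformat(ref.STUDY_START)
    end_date: dt.date = dt.date.fromisoformat(ref.STUDY_END)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ClinicGeneratorConfig":
        _simplex(self.failure_reason_weights, "failure_reason_weights")
        _simplex(self.purpose_weights, "purpose_weights")
        _simplex(self.activity_group_weights, "activity_group_weights")
        if abs(sum(self.activities_per_visit_weights) - 1.0) > 1e-9:
            raise ValueError("activities_per_visit_weights must sum to 1")
        if VisitOutcome.SUCCESS in self.failure_reason_weights:
            raise ValueError("failure_reason_weights must not include success")
        if ActivityGroup.TRAVEL in self.activity_group_weights:
            raise ValueError("activity_group_weights covers non-travel groups only")
        if self.end_date < self.start_date:
            raise ValueError("end_date before start_date")
        return self


def _dist(stats: tuple) -> DistSpec:
    _, _, median, (q1, q3) = stats
    return DistSpec(median=median, q1=q1, q3=q3)


def default_clinic_configs() -> tuple[ClinicGeneratorConfig, ClinicGeneratorConfig]:
    """Generator configurations calibrated to the two study clinics.

    Clinic 1 (peri-urban, 7 pairs): 97.3% visit success, ~1.8 patients per
    household, short travel legs (median 8 min).  Clinic 2 (urban informal
    settlement, 4 pairs): 71.5% success, ~1.2 patients per household, longer
    travel (median 14 min).  Failure-reason weights are proportional to the
    observed counts; roughly one form in five is corrupted, mirroring the
    ~20% of submitted forms excluded at validation.
    """
    configs = []
    for profile in ref.CLINIC_PROFILES:
        cid = profile.clinic_id
        totals = ref.WORKLOAD_TOTALS[cid]
        act = ref.ACTIVITY_STATS[cid]
        fails = ref.FAILURE_COUNTS[cid]
        n_fail = sum(fails.values())
        non_travel_counts = {
            g: act[g][0] for g in ActivityGroup if g is not ActivityGroup.TRAVEL
        }
        n_non_travel = sum(non_travel_counts.values())
        # mean activities per successful visit differs markedly by clinic
        # (~1.8 at clinic 1, ~0.9 at clinic 2)
        apv = (0.45, 0.35, 0.20) if cid == ref.CLINIC_1 else (1.0, 0.0, 0.0)
        configs.append(
            ClinicGeneratorConfig(
                clinic_profile=profile,
                days_per_pair=round(totals["tam_days_used"] / profile.n_pairs),
                daily_field_minutes=DistSpec(
                    median=totals["median_field_minutes"],
                    q1=totals["field_minutes_iqr"][0],
                    q3=totals["field_minutes_iqr"][1],
                ),
                field_minutes_clip=totals["field_minutes_range"],
                travel_minutes=_dist(act[ActivityGroup.TRAVEL]),
                visit_minutes_by_group={
                    g: _dist(act[g])
                    for g in ActivityGroup
                    if g is not ActivityGroup.TRAVEL
                },
                p_success=ref.P_SUCCESS[cid],
                failure_reason_weights={r: fails[r] / n_fail for r in FAILURE_REASONS},
                patients_per_household=TruncatedPoissonSpec(
                    lam=ref.PATIENTS_PER_HOUSEHOLD[cid] - 1.0
                ),
                purpose_weights=dict(ref.PURPOSE_SHARES[cid]),
                activity_group_weights={
                    g: c / n_non_travel for g, c in non_travel_counts.items()
                },
                activities_per_visit_weights=apv,
                p_corrupt_form=0.2,
            )
        )
    return tuple(configs)


def _choice(rng: np.random.Generator, weights: Mapping) -> object:
    keys = list(weights)
    p = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _build_pair_day(
    cfg: ClinicGeneratorConfig, rng: np.random.Generator, form_id: str,
    pair_id: str, date: dt.date,
) -> DailyForm:
    lo, hi = cfg.field_minutes_clip
    target = int(np.clip(round(float(cfg.daily_field_minutes.sample(rng))), lo, hi))
    depart = 7 * 60 + int(rng.integers(0, 25)) * 5  # 07:00-09:00 on a 5-min grid

    # the day is a renewal process of travel+visit cycles that stops once it
    # passes its threshold, so it overshoots by about half a cycle on
    # average; lower the stopping threshold accordingly to keep the realized
    # field time centered on the drawn target
    bundle_mean = (
        sum(
            w * cfg.visit_minutes_by_group[g].mean
            for g, w in cfg.activity_group_weights.items()
        )
        * sum((k + 1) * w for k, w in enumerate(cfg.activities_per_visit_weights))
    )
    travel_mean = cfg.travel_minutes.mean
    visit_part = cfg.p_success * bundle_mean
    cycle_mean = travel_mean + visit_part
    # when the threshold is crossed inside a visit a full return leg is still
    # appended, so discount that too
    p_end_in_visit = visit_part / cycle_mean
    threshold = max(
        travel_mean, target - cycle_mean / 2 - p_end_in_visit * travel_mean
    )

    # blocks: (group, visit_id, duration); always opens/closes with travel
    blocks: list[tuple[ActivityGroup, str | None, int]] = []
    visits: list[HouseholdVisit] = []
    total = 0
    while total < threshold:
        leg = cfg.travel_minutes.sample_minutes(rng)
        blocks.append((ActivityGroup.TRAVEL, None, leg))
        total += leg
        if total >= threshold:
            break
        visit_id = f"{form_id}-v{len(visits) + 1:02d}"
        if rng.random() < cfg.p_success:
            n_patients = cfg.patients_per_household.sample(rng)
            purpose = _choice(rng, cfg.purpose_weights)
            visits.append(
                HouseholdVisit(
                    visit_id=visit_id,
                    daily_form_id=form_id,
                    outcome=VisitOutcome.SUCCESS,
                    n_patients=n_patients,
                    purpose=purpose,
                )
            )
            n_acts = 1 + int(
                rng.choice(3, p=np.asarray(cfg.activities_per_visit_weights))
            )
            for _ in range(n_acts):
                group = _choice(rng, cfg.activity_group_weights)
                dur = cfg.visit_minutes_by_group[group].sample_minutes(rng)
                blocks.append((group, visit_id, dur))
                total += dur
        else:
            reason = _choice(rng, cfg.failure_reason_weights)
            visits.append(
                HouseholdVisit(
                    visit_id=visit_id,
                    daily_form_id=form_id,
                    outcome=reason,
                    n_patients=0,
                    purpose=None,
                )
            )
            # the brief doorstep interval is absorbed into the recorded
            # travel episode (extended only if the leg was shorter than the
            # doorstep itself); failed visits never accrue direct time
            if cfg.doorstep_minutes:
                g, v, d = blocks[-1]
                if d < cfg.doorstep_minutes + 1:
                    extra = cfg.doorstep_minutes + 1 - d
                    blocks[-1] = (g, v, d + extra)
                    total += extra
    if blocks[-1][0] is not ActivityGroup.TRAVEL:
        leg = cfg.travel_minutes.sample_minutes(rng)  # return to clinic
        blocks.append((ActivityGroup.TRAVEL, None, leg))
        total += leg

    records = []
    clock = depart
    for i, (group, visit_id, dur) in enumerate(blocks, start=1):
        records.append(
            ActivityRecord(
                record_id=f"{form_id}-r{i:03d}",
                daily_form_id=form_id,
                code=group.value,
                start=clock,
                end=clock + dur,
                visit_id=visit_id,
            )
        )
        clock += dur

    form = DailyForm(
        daily_form_id=form_id,
        pair_id=pair_id,
        clinic_id=cfg.clinic_profile.clinic_id,
        date=date,
        depart=depart,
        return_time=clock,
        visits=tuple(visits),
        records=tuple(records),
    )

    if cfg.p_corrupt_form > 0 and rng.random() < cfg.p_corrupt_form:
        form = _corrupt(form, rng)
    return form


def _corrupt(form: DailyForm, rng: np.random.Generator) -> DailyForm:
    """Inject one of the poor-quality patterns the validation rules catch."""
    records = list(form.records)
    if rng.random() < 0.5 and len(records) >= 2:
        # drop an interior record -> time gap
        del records[int(rng.integers(0, len(records) - 1))]
        return DailyForm(
            daily_form_id=form.daily_form_id, pair_id=form.pair_id,
            clinic_id=form.clinic_id, date=form.date, depart=form.depart,
            return_time=form.return_time, visits=form.visits,
            records=tuple(records),
        )
    # flatten every activity to an equal duration (suspicious pattern);
    # the form stays contiguous
    dur = 10
    clock = form.depart
    flat = []
    for r in records:
        flat.append(
            ActivityRecord(
                record_id=r.record_id, daily_form_id=r.daily_form_id, code=r.code,
                start=clock, end=clock + dur, visit_id=r.visit_id,
            )
        )
        clock += dur
    return DailyForm(
        daily_form_id=form.daily_form_id, pair_id=form.pair_id,
        clinic_id=form.clinic_id, date=form.date, depart=form.depart,
        return_time=clock, visits=form.visits, records=tuple(flat),
    )


def generate_dataset(
    configs: Sequence[ClinicGeneratorConfig], seed: int
) -> TamDataset:
    """Generate a linked TAM dataset for the configured clinics.

    Each pair contributes ``days_per_pair`` distinct field dates spread
    uniformly over the configured window.  Deterministic: identical
    (configs, seed) give identical datasets.
    """
    forms: list[DailyForm] = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(configs))
    for cfg, child in zip(configs, children):
        rng = np.random.default_rng(child)
        n_days = (cfg.end_date - cfg.start_date).days + 1
        all_dates = [cfg.start_date + dt.timedelta(days=i) for i in range(n_days)]
        for pair_idx in range(1, cfg.clinic_profile.n_pairs + 1):
            pair_id = f"{cfg.clinic_profile.clinic_id}-p{pair_idx}"
            picks = sorted(
                rng.choice(n_days, size=min(cfg.days_per_pair, n_days), replace=False)
            )
            for day_idx, pick in enumerate(picks, start=1):
                form_id = f"{pair_id}-d{day_idx:03d}"
                forms.append(
                    _build_pair_day(cfg, rng, form_id, pair_id, all_dates[int(pick)])
                )
    forms.sort(key=lambda f: (f.pair_id, f.date, f.daily_form_id))
    return TamDataset(
        forms=tuple(forms),
        clinics=tuple(cfg.clinic_profile for cfg in configs),
    )


# ---------------------------------------------------------------------------
# cost register

# Itemized split of each clinic's annual cost totals (USD/yr after
# annualization).  Capital items carry the life over which their purchase
# price is depreciated; the stored ZAR price is annual_usd x life x fx so the
# straight-line annualization recovers the category totals exactly.
_REGISTER_SPLITS: dict[str, list[tuple[str, CostCategory, str, int | None]]] = {
    ref.CLINIC_1: [
        ("Bicycles", CostCategory.EQUIPMENT, "1200", 4),
        ("Backpacks and field kits", CostCategory.EQUIPMENT, "880", 2),
        ("Mobile phones", CostCategory.EQUIPMENT, "800", 3),
        ("CCG stipends", CostCategory.STAFF, "46200", None),
        ("Team leader salary share", CostCategory.STAFF, "6743", None),
        ("Supervisor salary share", CostCategory.STAFF, "2000", None),
        ("Gloves and masks", CostCategory.CONSUMABLES, "2000", None),
        ("Forms and stationery", CostCategory.CONSUMABLES, "1200", None),
        ("Screening consumables", CostCategory.CONSUMABLES, "772", None),
        ("Clinic overhead allocation", CostCategory.OVERHEAD, "7496", None),
        ("Training and materials", CostCategory.IMPLEMENTATION, "2457", 5),
    ],
    ref.CLINIC_2: [
        ("Bicycles", CostCategory.EQUIPMENT, "800", 4),
        ("Backpacks and field kits", CostCategory.EQUIPMENT, "566", 2),
        ("Mobile phones", CostCategory.EQUIPMENT, "400", 3),
        ("CCG stipends", CostCategory.STAFF, "31500", None),
        ("Team leader salary share", CostCategory.STAFF, "4002", None),
        ("Supervisor salary share", CostCategory.STAFF, "2000", None),
        ("Gloves and masks", CostCategory.CONSUMABLES, "1200", None),
        ("Forms and stationery", CostCategory.CONSUMABLES, "700", None),
        ("Screening consumables", CostCategory.CONSUMABLES, "370", None),
        ("Clinic overhead allocation", CostCategory.OVERHEAD, "5434", None),
        ("Training and materials", CostCategory.IMPLEMENTATION, "2093", 5),
    ],
}


def _items_for(
    clinic_id: str, fx: Decimal, include_building: bool
) -> list[CostItem]:
    items = []
    for i, (label, cat, annual_usd, life) in enumerate(
        _REGISTER_SPLITS[clinic_id], start=1
    ):
        annual = Decimal(annual_usd)
        price = annual * fx * (life if life else 1)
        items.append(
            CostItem(
                item_id=f"{clinic_id}-c{i:02d}",
                label=label,
                category=cat,
                clinic_id=clinic_id,
                price_zar=price,
                is_capital=life is not None,
                life_years=life,
            )
        )
    if include_building:
        items.append(
            CostItem(
                item_id=f"{clinic_id}-bld",
                label="Office space allocation",
                category=CostCategory.BUILDING,
                clinic_id=clinic_id,
                price_zar=ref.ANNUAL_COST_TOTALS_USD[clinic_id]["building"] * fx,
            )
        )
    return items


def generate_cost_register(
    template: Literal["clinic1_like", "clinic2_like"],
    seed: int = 0,
    fx_zar_per_usd: Decimal = Decimal("14.448"),
) -> tuple[CostItem, ...]:
    """A single-clinic cost register whose category totals, once annualized,
    equal that clinic's published annual cost totals.

    The seed only shuffles item order; totals are exact by construction.
    """
    if template == "clinic1_like":
        clinic_id = ref.CLINIC_1
    elif template == "clinic2_like":
        clinic_id = ref.CLINIC_2
    else:
        raise ValueError(f"unknown template {template!r}")
    items = _items_for(clinic_id, fx_zar_per_usd, include_building=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    return tuple(items[i] for i in order)


def default_cost_register(
    seed: int = 0, fx_zar_per_usd: Decimal = Decimal("14.448")
) -> tuple[CostItem, ...]:
    """The two-clinic register, with building space as one shared item.

    The shared item's annual value (64.92 USD) splits equally between the
    clinics, so each carries 32.46 USD/yr of building cost.
    """
    items = _items_for(ref.CLINIC_1, fx_zar_per_usd, include_building=False)
    items += _items_for(ref.CLINIC_2, fx_zar_per_usd, include_building=False)
    building_total = (
        ref.ANNUAL_COST_TOTALS_USD[ref.CLINIC_1]["building"]
        + ref.ANNUAL_COST_TOTALS_USD[ref.CLINIC_2]["building"]
    )
    items.append(
        CostItem(
            item_id="shared-bld",
            label="Shared office space",
            category=CostCategory.BUILDING,
            clinic_id=SHARED,
            price_zar=building_total * fx_zar_per_usd,
        )
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    return tuple(items[i] for i in order)


# ---------------------------------------------------------------------------
# YAML round-trip for generator configs

def _config_to_dict(cfg: ClinicGeneratorConfig) -> dict:
    d = cfg.model_dump(mode="json")
    d["clinic_profile"] = {
        "clinic_id": cfg.clinic_profile.clinic_id,
        "setting": cfg.clinic_profile.setting,
        "catchment_km2": cfg.clinic_profile.catchment_km2,
        "households_registered": cfg.clinic_profile.households_registered,
        "n_pairs": cfg.clinic_profile.n_pairs,
        "n_team_members": cfg.clinic_profile.n_team_members,
        "n_supervisors": cfg.clinic_profile.n_supervisors,
    }
    return d


def configs_to_yaml(configs: Sequence[ClinicGeneratorConfig]) -> str:
    return yaml.safe_dump(
        {"clinics": [_config_to_dict(c) for c in configs]}, sort_keys=False
    )


def configs_from_yaml(text: str) -> tuple[ClinicGeneratorConfig, ...]:
    raw = yaml.safe_load(text)
    out = []
    for entry in raw["clinics"]:
        entry = dict(entry)
        entry["clinic_profile"] = ClinicProfile(**entry["clinic_profile"])
        out.append(ClinicGeneratorConfig(**entry))
    return tuple(out)
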