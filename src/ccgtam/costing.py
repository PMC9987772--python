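"""Activity-based costing of CCG outreach operations.

Implements the health-system-perspective costing model: capital goods are
annualized over their expected life-years (straight-line by default, with an
annuitized equivalent-annual-cost mode available), local-currency (ZAR)
amounts are converted to USD at a fixed exchange rate, costs are aggregated
by category and clinic, and unit costs are derived both top-down (aggregate
cost divided by operating time / visit volume) and bottom-up (costs
apportioned to individual CCG pairs from their observed person-minutes).

Money is held as exact ``Decimal`` throughout; division keeps full decimal
precision, and rounding to the cent happens only at presentation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tam_data import ActivityGroup, TamDataset

__all__ = [
    "CostCategory",
    "CATEGORIES",
    "SHARED",
    "CostItem",
    "CostingParams",
    "UnitCostTable",
    "ClinicWorkload",
    "TopDownCosts",
    "BottomUpCosts",
    "to_usd",
    "annualize",
    "aggregate_category_costs",
    "top_down_unit_costs",
    "bottom_up_costs",
    "cost_per_visit_curve",
    "read_cost_register",
    "write_cost_register",
]


class CostCategory(str, enum.Enum):
    EQUIPMENT = "equipment"
    STAFF = "staff"
    CONSUMABLES = "consumables"
    OVERHEAD = "overhead"
    IMPLEMENTATION = "implementation"
    BUILDING = "building"


CATEGORIES: tuple[CostCategory, ...] = tuple(CostCategory)

#: Sentinel clinic id for resources shared across clinics (e.g. office space).
SHARED = "shared"

_CENT = Decimal("0.01")
_TENTH_CENT_SQ = Decimal("0.0001")  # hundredth of a cent, internal resolution


def round_cents(amount: Decimal) -> Decimal:
    """Presentation rounding to the cent (half-up, as money is printed)."""
    from decimal import ROUND_HALF_UP

    return amount.quantize(_CENT, rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class CostItem:
    """One resource in the cost register.

    ``price_zar`` is the purchase price for capital goods and the annual
    amount for recurrent ones.  Capital goods carry an expected useful life
    in whole years (assumed 2-5 years for field equipment).
    """

    item_id: str
    label: str
    category: CostCategory
    clinic_id: str  # a clinic id, or SHARED
    price_zar: Decimal
    is_capital: bool = False
    life_years: int | None = None
    quantity: int = 1

    def __post_init__(self) -> None:
        if self.price_zar < 0:
            raise ValueError(f"{self.item_id}: negative price")
        if self.is_capital:
            if self.life_years is None or self.life_years < 1:
                raise ValueError(f"{self.item_id}: capital item needs life_years >= 1")
        if self.quantity < 1:
            raise ValueError(f"{self.item_id}: quantity must be >= 1")


@dataclass(frozen=True)
class CostingParams:
    """Global costing assumptions.

    Defaults reflect the study conditions: 250 working days/year of 8 hours,
    of which 235 minutes/day are field activity (household visits + travel);
    5%/yr discount rate; 14.448 ZAR per USD (World Bank, 2019).
    """

    discount_rate: Decimal = Decimal("0.05")
    working_days: int = 250
    hours_per_day: int = 8
    field_minutes_per_day: int = 235
    fx_zar_per_usd: Decimal = Decimal("14.448")
    annualization_mode: str = "straight_line"  # or "annuitized"

    def __post_init__(self) -> None:
        if not (0 <= self.discount_rate < 1):
            raise ValueError("discount_rate must be in [0, 1)")
        for name in ("working_days", "hours_per_day", "field_minutes_per_day"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fx_zar_per_usd <= 0:
            raise ValueError("fx_zar_per_usd must be positive")
        if self.annualization_mode not in ("straight_line", "annuitized"):
            raise ValueError(f"unknown annualization_mode {self.annualization_mode!r}")

    @property
    def minutes_per_day(self) -> int:
        return self.hours_per_day * 60

    @property
    def annual_minutes(self) -> int:
        return self.working_days * self.minutes_per_day


def to_usd(amount_zar: Decimal | int | str, params: CostingParams) -> Decimal:
    """Convert a ZAR amount to USD at the configured exchange rate."""
    amount = Decimal(amount_zar)
    if amount < 0:
        raise ValueError("negative amount")
    return amount / params.fx_zar_per_usd


def annualize_zar(item: CostItem, params: CostingParams) -> Decimal:
    """Annual ZAR cost of one register item (before currency conversion)."""
    total = item.price_zar * item.quantity
    if not item.is_capital:
        return total
    life = item.life_years
    assert life is not None and life >= 1
    if params.annualization_mode == "straight_line":
        return total / life
    r = params.discount_rate
    if r == 0:  # annuity factor degenerates to straight line
        return total / life
    annuity_factor = (1 - (1 + r) ** (-life)) / r
    return total / annuity_factor


def annualize(item: CostItem, params: CostingParams) -> Decimal:
    """Annual USD cost of one register item.

    Recurrent items pass through unchanged (converted); capital items are
    straight-line depreciated over their life-years, or converted to an
    equivalent annual cost with the annuity factor ``r / (1 - (1+r)^-L)``
    when ``annualization_mode == "annuitized"``.
    """
    return to_usd(annualize_zar(item, params), params)


@dataclass(frozen=True)
class UnitCostTable:
    """Per-clinic, per-category annual/daily/field-day/per-pair USD costs.

    The derived columns satisfy, exactly in decimal arithmetic:
    ``daily = annual / working_days``;
    ``daily_field = daily × field_minutes_per_day / (hours_per_day × 60)``;
    ``per_pair_annual = annual / n_pairs``.
    """

    params: CostingParams
    n_pairs: Mapping[str, int]
    annual_usd: Mapping[tuple[str, CostCategory], Decimal]

    @property
    def clinics(self) -> tuple[str, ...]:
        return tuple(sorted(self.n_pairs))

    def annual(self, clinic: str, category: CostCategory | None = None) -> Decimal:
        if category is not None:
            return self.annual_usd.get((clinic, category), Decimal(0))
        return sum(
            (self.annual_usd.get((clinic, c), Decimal(0)) for c in CATEGORIES),
            Decimal(0),
        )

    def daily(self, clinic: str, category: CostCategory | None = None) -> Decimal:
        return self.annual(clinic, category) / self.params.working_days

    def daily_field(self, clinic: str, category: CostCategory | None = None) -> Decimal:
        return (
            self.daily(clinic, category)
            * self.params.field_minutes_per_day
            / self.params.minutes_per_day
        )

    def per_pair_annual(
        self, clinic: str, category: CostCategory | None = None
    ) -> Decimal:
        return self.annual(clinic, category) / self.n_pairs[clinic]

    def cost_per_minute(
        self, clinic: str, category: CostCategory | None = None
    ) -> Decimal:
        """Top-down USD per person-minute of clinic operating time."""
        return self.annual(clinic, category) / self.params.annual_minutes

    def cost_per_pair_day(self, clinic: str) -> Decimal:
        return self.annual(clinic) / (self.n_pairs[clinic] * self.params.working_days)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with a Total row per clinic, rounded to the cent."""
        rows = []
        for clinic in self.clinics:
            for cat in CATEGORIES:
                rows.append(
                    {
                        "clinic_id": clinic,
                        "category": cat.value,
                        "annual_usd": round_cents(self.annual(clinic, cat)),
                        "daily_usd": round_cents(self.daily(clinic, cat)),
                        "daily_field_usd": round_cents(self.daily_field(clinic, cat)),
                        "per_pair_annual_usd": round_cents(
                            self.per_pair_annual(clinic, cat)
                        ),
                    }
                )
            rows.append(
                {
                    "clinic_id": clinic,
                    "category": "total",
                    "annual_usd": round_cents(self.annual(clinic)),
                    "daily_usd": round_cents(self.daily(clinic)),
                    "daily_field_usd": round_cents(self.daily_field(clinic)),
                    "per_pair_annual_usd": round_cents(self.per_pair_annual(clinic)),
                }
            )
        return pd.DataFrame(rows)


def aggregate_category_costs(
    items: Sequence[CostItem],
    params: CostingParams,
    n_pairs: Mapping[str, int],
    shared_weights: Mapping[str, float] | None = None,
) -> UnitCostTable:
    """Annualize and aggregate register items by clinic and category.

    Items marked ``shared`` are split equally between the clinics in
    *n_pairs* by default, or proportionally to *shared_weights* (e.g.
    observed person-minutes) when given.  ZAR amounts are summed first and
    converted to USD once, so no per-item rounding drift accrues.
    """
    clinics = sorted(n_pairs)
    if not clinics:
        raise ValueError("n_pairs must name at least one clinic")
    if shared_weights is not None:
        total_w = sum(shared_weights.get(c, 0.0) for c in clinics)
        if total_w <= 0:
            raise ValueError("shared_weights must have positive total")
        split = {c: Decimal(str(shared_weights.get(c, 0.0) / total_w)) for c in clinics}
    else:
        split = {c: Decimal(1) / len(clinics) for c in clinics}

    zar: dict[tuple[str, CostCategory], Decimal] = {}
    for item in items:
        if not isinstance(item.category, CostCategory):
            raise ValueError(f"unknown category {item.category!r}")
        annual = annualize_zar(item, params)
        if item.clinic_id == SHARED:
            for c in clinics:
                key = (c, item.category)
                zar[key] = zar.get(key, Decimal(0)) + annual * split[c]
        else:
            if item.clinic_id not in n_pairs:
                raise ValueError(f"item {item.item_id}: unknown clinic {item.clinic_id!r}")
            key = (item.clinic_id, item.category)
            zar[key] = zar.get(key, Decimal(0)) + annual
    annual_usd = {key: value / params.fx_zar_per_usd for key, value in zar.items()}
    return UnitCostTable(params=params, n_pairs=dict(n_pairs), annual_usd=annual_usd)


@dataclass(frozen=True)
class ClinicWorkload:
    """The TAM quantities the top-down model needs for one clinic."""

    clinic_id: str
    mean_minutes_by_group: Mapping[ActivityGroup, float]
    successful_visits_per_pair_day: float


@dataclass(frozen=True)
class TopDownCosts:
    clinic_id: str
    cost_per_minute: float
    cost_per_minute_by_category: Mapping[CostCategory, float]
    cost_per_activity: Mapping[ActivityGroup, float]
    cost_per_pair_day: float
    cost_per_visit: float


def top_down_unit_costs(
    table: UnitCostTable, params: CostingParams, workload: ClinicWorkload
) -> TopDownCosts:
    """Top-down unit costs: aggregate cost spread over operating time.

    Cost per minute divides the clinic's annual total by annual operating
    minutes (working_days × hours × 60); per-activity costs multiply it by
    the activity's mean observed duration; cost per pair-day divides the
    annual total over pair-days; cost per successful visit divides the
    pair-day cost by the mean number of successful visits per pair-day.
    """
    clinic = workload.clinic_id
    if workload.successful_visits_per_pair_day <= 0:
        raise ValueError("successful_visits_per_pair_day must be positive")
    cpm = float(table.cost_per_minute(clinic))
    per_cat = {c: float(table.cost_per_minute(clinic, c)) for c in CATEGORIES}
    per_act = {
        g: cpm * m for g, m in workload.mean_minutes_by_group.items()
    }
    cppd = float(table.cost_per_pair_day(clinic))
    return TopDownCosts(
        clinic_id=clinic,
        cost_per_minute=cpm,
        cost_per_minute_by_category=per_cat,
        cost_per_activity=per_act,
        cost_per_pair_day=cppd,
        cost_per_visit=cppd / workload.successful_visits_per_pair_day,
    )


@dataclass(frozen=True)
class BottomUpCosts:
    clinic_id: str
    clinic_annual_total: Decimal
    per_pair_annual: Mapping[str, Decimal]
    per_pair_day: Mapping[str, Decimal]
    mean_per_pair_annual: Decimal
    mean_per_pair_day: Decimal
    per_successful_visit: float
    warnings: tuple[str, ...] = ()


def bottom_up_costs(
    items: Sequence[CostItem],
    dataset: TamDataset,
    params: CostingParams,
    n_pairs: Mapping[str, int] | None = None,
) -> dict[str, BottomUpCosts]:
    """Bottom-up costs: apportion resources to individual CCG pairs.

    Staff costs (salaries) attach to pairs directly and are split equally;
    all other clinic costs, and the clinic's share of shared resources, are
    apportioned to pairs proportionally to each pair's observed
    person-minutes in the TAM data.  Per-pair shares are quantized to a
    hundredth of a cent with the residual assigned to the first pair, so
    pair costs sum to the clinic total exactly.

    ``per_successful_visit`` annualizes the observed visit rate: clinic
    annual total ÷ (mean successful visits per pair-day × n_pairs ×
    working_days).
    """
    clinic_ids = dataset.clinic_ids()
    if not clinic_ids:
        raise ValueError("dataset has no forms")
    if n_pairs is None:
        if dataset.clinics:
            n_pairs = {c.clinic_id: c.n_pairs for c in dataset.clinics}
        else:
            n_pairs = {
                cid: len({f.pair_id for f in dataset.forms_for_clinic(cid)})
                for cid in clinic_ids
            }
    table = aggregate_category_costs(items, params, n_pairs)

    results: dict[str, BottomUpCosts] = {}
    for clinic in clinic_ids:
        forms = dataset.forms_for_clinic(clinic)
        pairs = sorted({f.pair_id for f in forms})
        minutes = {p: 0 for p in pairs}
        successes = 0
        for f in forms:
            minutes[f.pair_id] += sum(r.duration for r in f.records)
            successes += sum(1 for v in f.visits if v.successful)
        warnings: list[str] = []
        zero_pairs = [p for p in pairs if minutes[p] == 0]
        if zero_pairs:
            warnings.append(
                f"pairs with zero observed minutes receive no apportioned share: "
                f"{', '.join(zero_pairs)}"
            )
        total_minutes = sum(minutes.values())
        if total_minutes == 0:
            raise ValueError(f"clinic {clinic}: no observed person-minutes")

        staff_total = table.annual(clinic, CostCategory.STAFF)
        other_total = table.annual(clinic) - staff_total

        shares: dict[str, Decimal] = {}
        for p in pairs:
            staff_share = staff_total / len(pairs)
            prop = Decimal(minutes[p]) / Decimal(total_minutes)
            other_share = other_total * prop
            shares[p] = (staff_share + other_share).quantize(_TENTH_CENT_SQ)
        residual = table.annual(clinic).quantize(_TENTH_CENT_SQ) - sum(
            shares.values(), Decimal(0)
        )
        shares[pairs[0]] += residual  # conservation to the hundredth of a cent

        clinic_total = sum(shares.values(), Decimal(0))
        per_pair_day = {
            p: v / params.working_days for p, v in shares.items()
        }
        mean_pair_annual = clinic_total / len(pairs)
        visits_per_pair_day = successes / len(forms)
        if visits_per_pair_day > 0:
            per_visit = float(clinic_total) / (
                visits_per_pair_day * n_pairs[clinic] * params.working_days
            )
        else:
            per_visit = float("nan")
            warnings.append("no successful visits observed; per-visit cost undefined")
        results[clinic] = BottomUpCosts(
            clinic_id=clinic,
            clinic_annual_total=clinic_total,
            per_pair_annual=shares,
            per_pair_day=per_pair_day,
            mean_per_pair_annual=mean_pair_annual,
            mean_per_pair_day=mean_pair_annual / params.working_days,
            per_successful_visit=per_visit,
            warnings=tuple(warnings),
        )
    return results


def cost_per_visit_curve(
    table: UnitCostTable,
    params: CostingParams,
    visits_per_day: Iterable[int],
) -> pd.DataFrame:
    """Average cost per successful household visit as visit volume varies.

    For a pair making ``v`` successful visits per day the average cost per
    visit is ``cost_per_pair_day / v`` — a strictly decreasing, convex curve
    (economies of scale with diminishing marginal savings).
    """
    vs = sorted(set(int(v) for v in visits_per_day))
    if not vs:
        raise ValueError("visits_per_day is empty")
    if vs[0] < 1:
        raise ValueError("visits_per_day values must be >= 1")
    rows = []
    for clinic in table.clinics:
        cppd = float(table.cost_per_pair_day(clinic))
        for v in vs:
            rows.append(
                {
                    "clinic_id": clinic,
                    "visits_per_day": v,
                    "cost_per_visit_usd": cppd / v,
                }
            )
    return pd.DataFrame(rows)


COST_COLUMNS = [
    "item_id",
    "label",
    "category",
    "clinic_id",
    "price_zar",
    "is_capital",
    "life_years",
    "quantity",
]


def read_cost_register(path: Path | str) -> tuple[CostItem, ...]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    items = []
    for row in df.itertuples(index=False):
        items.append(
            CostItem(
                item_id=row.item_id,
                label=row.label,
                category=CostCategory(row.category),
                clinic_id=row.clinic_id,
                price_zar=Decimal(row.price_zar),
                is_capital=row.is_capital.lower() in ("true", "1", "yes"),
                life_years=int(row.life_years) if row.life_years else None,
                quantity=int(row.quantity) if row.quantity else 1,
            )
        )
    return tuple(items)


def write_cost_register(items: Sequence[CostItem], path: Path | str) -> Path:
    rows = [
        {
            "item_id": it.item_id,
            "label": it.label,
            "category": it.category.value,
            "clinic_id": it.clinic_id,
            "price_zar": str(it.price_zar),
            "is_capital": str(it.is_capital).lower(),
            "life_years": it.life_years if it.life_years is not None else "",
            "quantity": it.quantity,
        }
        for it in items
    ]
    pd.DataFrame(rows, columns=COST_COLUMNS).to_csv(path, index=False)
    return Path(path)
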