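"""Costing engine: conversion, annualization, aggregation, unit costs, curve."""

from decimal import Decimal

import pytest

from ccgtam.costing import (
    CostCategory,
    CostItem,
    CostingParams,
    ClinicWorkload,
    SHARED,
    aggregate_category_costs,
    annualize,
    annualize_zar,
    bottom_up_costs,
    cost_per_visit_curve,
    read_cost_register,
    round_cents,
    to_usd,
    top_down_unit_costs,
    write_cost_register,
)
from ccgtam.synthetic import default_cost_register, generate_dataset
from ccgtam.tam_data import ActivityGroup

from .conftest import scaled_configs

PARAMS = CostingParams()
N_PAIRS = {"clinic1": 7, "clinic2": 4}


@pytest.fixture(scope="module")
def table():
    return aggregate_category_costs(default_cost_register(0), PARAMS, N_PAIRS)


@pytest.fixture(scope="module")
def dataset():
    return generate_dataset(scaled_configs(days_per_pair=6), seed=3)


def item(price, *, capital=False, life=None, category=CostCategory.EQUIPMENT,
         clinic="clinic1", qty=1, iid="x1"):
    return CostItem(
        item_id=iid, label="test", category=category, clinic_id=clinic,
        price_zar=Decimal(str(price)), is_capital=capital, life_years=life,
        quantity=qty,
    )


class TestToUsd:
    def test_stated_rate(self):
        assert to_usd(Decimal("14.448"), PARAMS) == 1

    def test_zero(self):
        assert to_usd(0, PARAMS) == 0

    def test_large_amount_to_the_cent(self):
        assert round_cents(to_usd(Decimal("1000000"), PARAMS)) == Decimal("69213.73")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            to_usd(Decimal("-1"), PARAMS)


class TestAnnualize:
    def test_straight_line_capital(self):
        it = item(10_000, capital=True, life=5)
        assert annualize_zar(it, PARAMS) == Decimal(2000)
        assert round_cents(annualize(it, PARAMS)) == Decimal("138.43")

    def test_recurrent_passthrough(self):
        it = item(14_448)
        assert annualize(it, PARAMS) == Decimal(1000)

    def test_annuitized_closed_form(self):
        params = CostingParams(annualization_mode="annuitized")
        it = item(1000, capital=True, life=5)
        assert round_cents(annualize_zar(it, params)) == Decimal("230.97")

    def test_zero_rate_annuity_equals_straight_line(self):
        annuity0 = CostingParams(annualization_mode="annuitized",
                                 discount_rate=Decimal("0"))
        it = item(9_999, capital=True, life=4)
        assert annualize_zar(it, annuity0) == annualize_zar(it, PARAMS)

    def test_quantity_multiplies(self):
        assert annualize_zar(item(100, qty=7), PARAMS) == Decimal(700)

    def test_capital_needs_life_years(self):
        with pytest.raises(ValueError):
            item(100, capital=True, life=0)


class TestAggregate:
    def test_published_daily_costs(self, table):
        assert round_cents(table.daily("clinic1", CostCategory.EQUIPMENT)) == (
            Decimal("11.52")
        )
        assert round_cents(table.daily("clinic1", CostCategory.STAFF)) == (
            Decimal("219.77")
        )

    def test_published_field_day_cost(self, table):
        assert round_cents(table.daily_field("clinic1", CostCategory.STAFF)) == (
            Decimal("107.60")
        )

    def test_daily_times_working_days_is_annual(self, table):
        for clinic in table.clinics:
            for cat in CostCategory:
                assert round_cents(table.daily(clinic, cat) * 250) == round_cents(
                    table.annual(clinic, cat)
                )

    def test_shared_building_splits_equally(self, table):
        for clinic in N_PAIRS:
            assert round_cents(table.annual(clinic, CostCategory.BUILDING)) == (
                Decimal("32.46")
            )

    def test_per_pair_annual_totals(self, table):
        assert round_cents(table.per_pair_annual("clinic1")) == Decimal("10254.35")
        assert round_cents(table.per_pair_annual("clinic2")) == Decimal("12274.37")

    def test_zero_items_zero_table(self):
        empty = aggregate_category_costs([], PARAMS, N_PAIRS)
        assert empty.annual("clinic1") == 0

    def test_scaling_prices_scales_costs(self):
        items = [item(1000), item(500, category=CostCategory.STAFF)]
        scaled = [
            CostItem(
                item_id=i.item_id, label=i.label, category=i.category,
                clinic_id=i.clinic_id, price_zar=i.price_zar * 3,
                is_capital=i.is_capital, life_years=i.life_years,
                quantity=i.quantity,
            )
            for i in items
        ]
        t1 = aggregate_category_costs(items, PARAMS, N_PAIRS)
        t3 = aggregate_category_costs(scaled, PARAMS, N_PAIRS)
        assert round_cents(t3.annual("clinic1")) == round_cents(
            3 * t1.annual("clinic1")
        )


class TestTopDown:
    def test_published_cost_per_pair_day(self):
        table = aggregate_category_costs(default_cost_register(0), PARAMS, N_PAIRS)
        td1 = top_down_unit_costs(
            table, PARAMS,
            ClinicWorkload("clinic1", {ActivityGroup.TRAVEL: 11.2}, 9.5),
        )
        td2 = top_down_unit_costs(
            table, PARAMS,
            ClinicWorkload("clinic2", {ActivityGroup.TRAVEL: 16.2}, 6.7),
        )
        assert td1.cost_per_pair_day == pytest.approx(41.02, abs=0.005)
        assert td2.cost_per_pair_day == pytest.approx(49.10, abs=0.005)

    def test_toy_clinic_per_visit(self):
        """Annual 1,200 USD, 1 pair, 250 days, 4 visits/day -> 1.20 per visit."""
        items = [item(Decimal("1200") * Decimal("14.448"), clinic="c")]
        table = aggregate_category_costs(items, PARAMS, {"c": 1})
        td = top_down_unit_costs(table, PARAMS, ClinicWorkload("c", {}, 4.0))
        assert td.cost_per_visit == pytest.approx(1.20)

    def test_homogeneity(self):
        items = [item(5000), item(2000, category=CostCategory.OVERHEAD)]
        doubled = [
            CostItem(
                item_id=i.item_id, label=i.label, category=i.category,
                clinic_id=i.clinic_id, price_zar=i.price_zar * 2,
                is_capital=i.is_capital, life_years=i.life_years,
                quantity=i.quantity,
            )
            for i in items
        ]
        wl = ClinicWorkload("clinic1", {ActivityGroup.TRAVEL: 10.0}, 5.0)
        t1 = top_down_unit_costs(
            aggregate_category_costs(items, PARAMS, N_PAIRS), PARAMS, wl
        )
        t2 = top_down_unit_costs(
            aggregate_category_costs(doubled, PARAMS, N_PAIRS), PARAMS, wl
        )
        assert t2.cost_per_minute == pytest.approx(2 * t1.cost_per_minute)
        assert t2.cost_per_visit == pytest.approx(2 * t1.cost_per_visit)

    def test_zero_visits_rejected(self):
        table = aggregate_category_costs([item(100)], PARAMS, N_PAIRS)
        with pytest.raises(ValueError):
            top_down_unit_costs(table, PARAMS, ClinicWorkload("clinic1", {}, 0.0))


class TestBottomUp:
    def test_per_pair_costs_conserve_clinic_total(self, dataset):
        results = bottom_up_costs(default_cost_register(0), dataset, PARAMS, N_PAIRS)
        table = aggregate_category_costs(default_cost_register(0), PARAMS, N_PAIRS)
        for clinic, res in results.items():
            assert sum(res.per_pair_annual.values()) == res.clinic_annual_total
            assert round_cents(res.clinic_annual_total) == round_cents(
                table.annual(clinic)
            )

    def test_mean_per_pair_matches_published(self, dataset):
        results = bottom_up_costs(default_cost_register(0), dataset, PARAMS, N_PAIRS)
        assert float(results["clinic1"].mean_per_pair_annual) == pytest.approx(
            10_254, abs=1
        )
        assert float(results["clinic2"].mean_per_pair_annual) == pytest.approx(
            12_274, abs=1
        )

    def test_single_pair_takes_all_costs(self):
        cfg = scaled_configs(days_per_pair=3)[0]
        profile = cfg.clinic_profile
        one_pair = cfg.model_copy(
            update={
                "clinic_profile": type(profile)(
                    clinic_id=profile.clinic_id, setting=profile.setting,
                    catchment_km2=profile.catchment_km2,
                    households_registered=profile.households_registered,
                    n_pairs=1, n_team_members=2, n_supervisors=1,
                )
            }
        )
        ds = generate_dataset((one_pair,), seed=2)
        items = [item(10_000), item(5_000, category=CostCategory.STAFF)]
        res = bottom_up_costs(items, ds, PARAMS, {"clinic1": 1})["clinic1"]
        assert len(res.per_pair_annual) == 1
        (share,) = res.per_pair_annual.values()
        assert share == res.clinic_annual_total


class TestCurve:
    def test_exact_reciprocal_shape(self, table):
        curve = cost_per_visit_curve(table, PARAMS, [2, 4, 8])
        c1 = curve[curve.clinic_id == "clinic1"].set_index("visits_per_day")
        assert c1.loc[4, "cost_per_visit_usd"] == pytest.approx(
            c1.loc[2, "cost_per_visit_usd"] / 2
        )
        assert c1.loc[8, "cost_per_visit_usd"] == pytest.approx(
            c1.loc[4, "cost_per_visit_usd"] / 2
        )

    def test_toy_division(self):
        items = [item(Decimal("10000") * Decimal("14.448"), clinic="c")]
        table = aggregate_category_costs(items, PARAMS, {"c": 1})
        assert float(table.cost_per_pair_day("c")) == pytest.approx(40.0)
        curve = cost_per_visit_curve(table, PARAMS, [10])
        assert curve["cost_per_visit_usd"].iloc[0] == pytest.approx(4.0)

    def test_clinic2_higher_and_gap_shrinks(self, table):
        curve = cost_per_visit_curve(table, PARAMS, range(1, 16))
        wide = curve.pivot(index="visits_per_day", columns="clinic_id",
                           values="cost_per_visit_usd")
        assert (wide["clinic2"] > wide["clinic1"]).all()
        gaps = (wide["clinic2"] - wide["clinic1"]).to_numpy()
        assert (gaps[1:] < gaps[:-1]).all()

    def test_monotone_decreasing_and_convex(self, table):
        curve = cost_per_visit_curve(table, PARAMS, range(1, 16))
        for _, sub in curve.groupby("clinic_id"):
            y = sub.sort_values("visits_per_day")["cost_per_visit_usd"].to_numpy()
            assert (y[1:] < y[:-1]).all()
            # diminishing marginal savings: second differences positive
            assert ((y[2:] - y[1:-1]) - (y[1:-1] - y[:-2]) > 0).all()

    def test_zero_visits_rejected(self, table):
        with pytest.raises(ValueError):
            cost_per_visit_curve(table, PARAMS, [0, 1])


def test_cost_register_roundtrip(tmp_path):
    items = default_cost_register(5)
    path = write_cost_register(items, tmp_path / "costs.csv")
    assert read_cost_register(path) == items
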