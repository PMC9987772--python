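"""End-to-end pipeline: simulate/load → validate → analyze → cost → report.

Produces the study's report bundle from any conforming dataset: per-clinic
operational characteristics (table1.csv), activity unit times (table2.csv),
category costs (table3.csv), unsuccessful-visit reasons (table4.csv), the
cost-per-visit economies-of-scale curve (curve.csv + figure), a machine
readable summary.json, and a run log.  The bundle is deterministic for a
fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import reference as ref
from .costing import (
    ClinicWorkload,
    CostItem,
    CostingParams,
    UnitCostTable,
    aggregate_category_costs,
    bottom_up_costs,
    cost_per_visit_curve,
    read_cost_register,
    top_down_unit_costs,
)
from .synthetic import (
    ClinicGeneratorConfig,
    default_clinic_configs,
    default_cost_register,
    generate_dataset,
)
from .tam_data import (
    ActivityGroup,
    QualityVerdict,
    TamDataset,
    apply_quality_filter,
    read_tam_dataset,
)
from .workload import (
    activity_unit_times,
    clinic_time_allocation,
    compare_medians,
    per_day_rates,
    summarize_days,
    tb_composition,
    visit_outcome_table,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "render_fig1"]

logger = logging.getLogger("ccgtam")


class RunConfig(BaseModel):
    """Configuration of one pipeline run.

    Either *input_dir* (holding daily.csv, visits.csv, activities.csv and
    optionally clinics.csv / costs.csv) or simulation configs must be given;
    with neither, the calibrated default clinic configurations are simulated.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    input_dir: Path | None = None
    sim_configs: tuple[ClinicGeneratorConfig, ...] | None = None
    simulate: bool = True
    costing: CostingParams = CostingParams()
    months_observed: int = ref.STUDY_MONTHS_OBSERVED
    curve_max_visits: int = 15
    out_dir: Path = Path("ccgtam-report")
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _sourced(self) -> "RunConfig":
        if self.input_dir is None and not self.simulate and self.sim_configs is None:
            raise ValueError("need input_dir or a simulation config")
        return self


@dataclass
class ReportBundle:
    out_dir: Path
    paths: Mapping[str, Path]
    dataset: TamDataset
    excluded: tuple[QualityVerdict, ...]
    cost_table: UnitCostTable
    summary: dict


def _r1(x: float) -> float:
    return round(float(x), 1)


def _build_table1(dataset, summaries, months_observed, seed) -> pd.DataFrame:
    rows = []
    for clinic in dataset.clinic_ids():
        alloc = clinic_time_allocation(summaries, clinic)
        rates = per_day_rates(summaries, clinic)
        outcomes = visit_outcome_table(dataset, clinic, months_observed)
        comp = tb_composition(dataset, clinic)
        clinic_days = [s for s in summaries if s.clinic_id == clinic]
        fm = sorted(s.field_minutes for s in clinic_days)
        med = pd.Series(fm).median()
        rows.append(
            {
                "clinic_id": clinic,
                "n_pair_days": len(clinic_days),
                "person_minutes": sum(s.field_minutes for s in clinic_days),
                "household_minutes": sum(s.household_minutes for s in clinic_days),
                "pct_household": _r1(alloc.pct_household),
                "pct_household_min": _r1(alloc.pct_household_range[0]),
                "pct_household_max": _r1(alloc.pct_household_range[1]),
                "median_field_minutes": _r1(med),
                "attempted_visits": outcomes.attempted,
                "successful_visits": outcomes.successful,
                "success_rate_pct": _r1(outcomes.success_rate_pct),
                "unsuccessful_visits": outcomes.failed,
                "failure_rate_pct": _r1(outcomes.failure_rate_pct),
                "households_per_day": _r1(rates.households_per_day),
                "patients_per_day": _r1(rates.patients_per_day),
                "patients_per_household": _r1(rates.patients_per_household),
                "minutes_per_patient": _r1(rates.minutes_per_patient),
                "pct_tb_only": _r1(comp.pct_tb_only),
                "pct_non_tb_only": _r1(comp.pct_non_tb_only),
                "pct_both": _r1(comp.pct_both),
            }
        )
    return pd.DataFrame(rows)


def _build_table2(dataset) -> pd.DataFrame:
    rows = []
    for clinic in dataset.clinic_ids():
        for row in activity_unit_times(dataset, clinic):
            rows.append(
                {
                    "clinic_id": clinic,
                    "group": row.group.value if row.group else "total",
                    "count": row.count,
                    "pct_count": _r1(row.pct_count),
                    "total_minutes": row.total_minutes,
                    "pct_minutes": _r1(row.pct_minutes),
                    "mean": _r1(row.mean),
                    "ci_low": _r1(row.ci_low),
                    "ci_high": _r1(row.ci_high),
                    "median": _r1(row.median),
                    "q1": _r1(row.q1),
                    "q3": _r1(row.q3),
                }
            )
    return pd.DataFrame(rows)


def _build_table4(dataset, months_observed) -> pd.DataFrame:
    rows = []
    for clinic in dataset.clinic_ids():
        table = visit_outcome_table(dataset, clinic, months_observed)
        for reason, (n, pct, per_month) in table.reasons.items():
            rows.append(
                {
                    "clinic_id": clinic,
                    "reason": reason.value,
                    "count": n,
                    "pct_of_attempts": _r1(pct),
                    "per_month": round(per_month, 2),
                }
            )
        rows.append(
            {
                "clinic_id": clinic,
                "reason": "total",
                "count": table.failed,
                "pct_of_attempts": _r1(table.failure_rate_pct),
                "per_month": round(table.failed / months_observed, 2),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run all stages and write the report bundle to ``config.out_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        line = f"[{stage}] {message}"
        logger.info(line)
        log_lines.append(line)

    log("config", f"seed={config.seed}")

    # --- stage 1: obtain data -------------------------------------------------
    items: Sequence[CostItem]
    try:
        if config.input_dir is not None:
            d = Path(config.input_dir)
            dataset = read_tam_dataset(
                d / "daily.csv", d / "activities.csv", d / "visits.csv",
                clinic_path=(d / "clinics.csv") if (d / "clinics.csv").exists() else None,
            )
            costs_path = d / "costs.csv"
            items = (
                read_cost_register(costs_path)
                if costs_path.exists()
                else default_cost_register(config.seed)
            )
            log("load", f"read {len(dataset)} forms from {d}")
        else:
            configs = config.sim_configs or default_clinic_configs()
            dataset = generate_dataset(configs, seed=config.seed)
            items = default_cost_register(config.seed)
            log("simulate", f"generated {len(dataset)} forms")
    except Exception as exc:
        raise RuntimeError(f"stage load/simulate failed: {exc}") from exc

    # --- stage 2: quality validation -----------------------------------------
    try:
        dataset, excluded = apply_quality_filter(dataset)
        log("validate", f"retained {len(dataset)} forms, excluded {len(excluded)}")
    except Exception as exc:
        raise RuntimeError(f"stage validate failed: {exc}") from exc

    # --- stage 3: workload analysis ------------------------------------------
    try:
        summaries = summarize_days(dataset)
        table1 = _build_table1(dataset, summaries, config.months_observed, config.seed)
        table2 = _build_table2(dataset)
        table4 = _build_table4(dataset, config.months_observed)
        travel = {
            clinic: [
                r.duration
                for f in dataset.forms_for_clinic(clinic)
                for r in f.records
                if not r.is_direct
            ]
            for clinic in dataset.clinic_ids()
        }
        log("workload", f"summarized {len(summaries)} pair-days")
    except Exception as exc:
        raise RuntimeError(f"stage workload failed: {exc}") from exc

    # --- stage 4: costing -----------------------------------------------------
    try:
        n_pairs = {c.clinic_id: c.n_pairs for c in dataset.clinics} or {
            cid: len({f.pair_id for f in dataset.forms_for_clinic(cid)})
            for cid in dataset.clinic_ids()
        }
        cost_table = aggregate_category_costs(items, config.costing, n_pairs)
        table3 = cost_table.to_frame()
        bottom_up = bottom_up_costs(items, dataset, config.costing, n_pairs)
        top_down = {}
        for clinic in dataset.clinic_ids():
            rates = per_day_rates(summaries, clinic)
            means = {
                row.group: row.mean
                for row in activity_unit_times(dataset, clinic)
                if row.group is not None and row.count > 0
            }
            top_down[clinic] = top_down_unit_costs(
                cost_table,
                config.costing,
                ClinicWorkload(
                    clinic_id=clinic,
                    mean_minutes_by_group=means,
                    successful_visits_per_pair_day=rates.households_per_day,
                ),
            )
        curve = cost_per_visit_curve(
            cost_table, config.costing, range(1, config.curve_max_visits + 1)
        )
        log("cost", f"aggregated {len(list(items))} register items")
    except Exception as exc:
        raise RuntimeError(f"stage cost failed: {exc}") from exc

    # --- stage 5: report ------------------------------------------------------
    clinics = list(dataset.clinic_ids())
    summary: dict = {
        "seed": config.seed,
        "forms": {
            "input": len(dataset) + len(excluded),
            "retained": len(dataset),
            "excluded": len(excluded),
        },
        "clinics": {},
    }
    for clinic in clinics:
        t1 = table1.set_index("clinic_id").loc[clinic]
        summary["clinics"][clinic] = {
            "pct_household": float(t1["pct_household"]),
            "median_field_minutes": float(t1["median_field_minutes"]),
            "success_rate_pct": float(t1["success_rate_pct"]),
            "households_per_day": float(t1["households_per_day"]),
            "patients_per_household": float(t1["patients_per_household"]),
            "minutes_per_patient": float(t1["minutes_per_patient"]),
            "annual_cost_usd": float(cost_table.annual(clinic)),
            "per_pair_annual_usd": float(cost_table.per_pair_annual(clinic)),
            "top_down_cost_per_pair_day_usd": top_down[clinic].cost_per_pair_day,
            "top_down_cost_per_visit_usd": top_down[clinic].cost_per_visit,
            "bottom_up_per_pair_day_usd": float(bottom_up[clinic].mean_per_pair_day),
            "bottom_up_cost_per_visit_usd": bottom_up[clinic].per_successful_visit,
        }
    if len(clinics) == 2:
        cmp = compare_medians(
            travel[clinics[0]], travel[clinics[1]], seed=config.seed
        )
        summary["travel_median_difference_minutes"] = {
            "estimate": cmp.estimate,
            "ci_low": round(cmp.ci_low, 2),
            "ci_high": round(cmp.ci_high, 2),
        }

    paths = {
        "table1": out / "table1.csv",
        "table2": out / "table2.csv",
        "table3": out / "table3.csv",
        "table4": out / "table4.csv",
        "curve": out / "curve.csv",
        "summary": out / "summary.json",
        "log": out / "run_log.txt",
    }
    table1.to_csv(paths["table1"], index=False)
    table2.to_csv(paths["table2"], index=False)
    table3.to_csv(paths["table3"], index=False)
    table4.to_csv(paths["table4"], index=False)
    curve.to_csv(paths["curve"], index=False, float_format="%.4f")
    paths["summary"].write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    log("report", f"bundle written to {out}")
    paths["log"].write_text("\n".join(log_lines) + "\n")

    return ReportBundle(
        out_dir=out,
        paths=paths,
        dataset=dataset,
        excluded=excluded,
        cost_table=cost_table,
        summary=summary,
    )


def render_fig1(curve: pd.DataFrame, path: Path | str) -> Path:
    """Plot average cost per successful visit against visits per day.

    One decreasing curve per clinic; requires at least two points per clinic.
    """
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if curve.empty:
        raise ValueError("curve data is empty")
    fig, ax = plt.subplots(figsize=(6, 4))
    for clinic, sub in curve.groupby("clinic_id"):
        if len(sub) < 2:
            raise ValueError(f"need >= 2 curve points for clinic {clinic!r}")
        ax.plot(sub["visits_per_day"], sub["cost_per_visit_usd"], marker="o",
                label=str(clinic))
    ax.set_xlabel("Successful household visits per pair-day")
    ax.set_ylabel("Average cost per visit (USD)")
    ax.legend(title="Clinic")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150, metadata={})
    plt.close(fig)
    return path
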