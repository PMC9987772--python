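import datetime as dt

import pytest

from ccgtam.synthetic import default_clinic_configs, generate_dataset
from ccgtam.tam_data import (
    ActivityRecord,
    DailyForm,
    HouseholdVisit,
    VisitOutcome,
    VisitPurpose,
)


def make_form(
    form_id="f1",
    pair_id="c1-p1",
    clinic_id="clinic1",
    date=dt.date(2018, 3, 5),
    depart=480,
    blocks=(("travel", None, 10), ("health_screening", "v1", 15)),
    visits=(("v1", VisitOutcome.SUCCESS, 2, VisitPurpose.NON_TB_ONLY),),
):
    """Build a contiguous daily form from (code, visit_id, duration) blocks."""
    records = []
    clock = depart
    for i, (code, visit_id, dur) in enumerate(blocks, start=1):
        records.append(
            ActivityRecord(
                record_id=f"{form_id}-r{i}",
                daily_form_id=form_id,
                code=code,
                start=clock,
                end=clock + dur,
                visit_id=visit_id,
            )
        )
        clock += dur
    vs = tuple(
        HouseholdVisit(
            visit_id=v, daily_form_id=form_id, outcome=o, n_patients=n, purpose=p
        )
        for v, o, n, p in visits
    )
    return DailyForm(
        daily_form_id=form_id,
        pair_id=pair_id,
        clinic_id=clinic_id,
        date=date,
        depart=depart,
        return_time=clock,
        visits=vs,
        records=tuple(records),
    )


def scaled_configs(days_per_pair, p_corrupt=0.0):
    """Default clinic configs with the observation length and corruption
    rate adjusted, e.g. for Monte-Carlo checks at larger n."""
    return tuple(
        cfg.model_copy(
            update={"days_per_pair": days_per_pair, "p_corrupt_form": p_corrupt}
        )
        for cfg in default_clinic_configs()
    )


@pytest.fixture(scope="session")
def clean_configs():
    """Study-calibrated configs with corruption switched off."""
    return scaled_configs(days_per_pair=14, p_corrupt=0.0)


@pytest.fixture(scope="session")
def small_dataset(clean_configs):
    """A clean study-sized two-clinic dataset (~150 pair-days)."""
    return generate_dataset(clean_configs, seed=20180301)


@pytest.fixture(scope="session")
def big_dataset():
    """>= 500 clean pair-days for parameter-recovery checks (7x75 + 4x75)."""
    return generate_dataset(scaled_configs(days_per_pair=75), seed=971)
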