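"""Published operational statistics of the two-clinic CCG study.

These are the printed summary figures from the Ekurhuleni (South Africa)
community-caregiver time-and-motion and costing study that this package
models: clinic characteristics, workload totals, activity unit times,
visit-outcome counts, and annual cost totals by category (USD 2019).  The
synthetic generator is calibrated against them, and the worked examples and
acceptance checks recompute the study's derived quantities from them.

Monetary values are USD per year unless noted; times are minutes.
"""

from __future__ import annotations

from decimal import Decimal
from types import MappingProxyType

from .tam_data import ActivityGroup, ClinicProfile, VisitOutcome, VisitPurpose

CLINIC_1 = "clinic1"
CLINIC_2 = "clinic2"

CLINIC_PROFILES = (
    ClinicProfile(
        clinic_id=CLINIC_1,
        setting="peri-urban",
        catchment_km2=3.1,
        households_registered=8035,
        n_pairs=7,
        n_team_members=15,
        n_supervisors=2,
    ),
    ClinicProfile(
        clinic_id=CLINIC_2,
        setting="urban informal settlement",
        catchment_km2=0.6,
        households_registered=5200,
        n_pairs=4,
        n_team_members=9,
        n_supervisors=1,
    ),
)

#: Workload totals over the observation period (March-October 2018), per clinic.
WORKLOAD_TOTALS = MappingProxyType(
    {
        CLINIC_1: MappingProxyType(
            {
                "tam_days_used": 101,
                "person_minutes": 23_786,
                "household_minutes": 11_772,
                "attempted_visits": 973,
                "successful_visits": 947,
                "unsuccessful_visits": 26,
                "patients": 1_756,
                "household_activities": 1_692,
                "median_field_minutes": 236,
                "field_minutes_iqr": (215, 261),
                "field_minutes_range": (105, 345),
            }
        ),
        CLINIC_2: MappingProxyType(
            {
                "tam_days_used": 58,
                "person_minutes": 15_881,
                "household_minutes": 5_558,
                "attempted_visits": 579,
                "successful_visits": 414,
                "unsuccessful_visits": 165,
                "patients": 460,
                "household_activities": 391,
                "median_field_minutes": 235,
                "field_minutes_iqr": (201, 272),
                "field_minutes_range": (114, 325),
            }
        ),
    }
)

#: Per-group activity statistics: (episode count, total person-minutes,
#: median duration, (q1, q3)).  Zero-count groups carry a placeholder
#: median/IQR that is never sampled.
ACTIVITY_STATS = MappingProxyType(
    {
        CLINIC_1: MappingProxyType(
            {
                ActivityGroup.ADHERENCE_SUPPORT_TB: (51, 451, 5, (5, 10)),
                ActivityGroup.ADHERENCE_SUPPORT_OTHER: (386, 2_633, 5, (3, 8)),
                ActivityGroup.CLIENT_ENCOUNTER_TB: (501, 3_380, 5, (3, 9)),
                ActivityGroup.CLIENT_ENCOUNTER_OTHER: (750, 5_246, 5, (3, 10)),
                ActivityGroup.HOME_BASED_CARE: (4, 62, 8, (5.5, 25.5)),
                ActivityGroup.TRAVEL: (1_073, 12_014, 8, (5, 15)),
            }
        ),
        CLINIC_2: MappingProxyType(
            {
                ActivityGroup.ADHERENCE_SUPPORT_TB: (5, 45, 8, (7, 11)),
                ActivityGroup.ADHERENCE_SUPPORT_OTHER: (97, 1_172, 11, (8, 15)),
                ActivityGroup.CLIENT_ENCOUNTER_TB: (17, 288, 16, (11, 22)),
                ActivityGroup.CLIENT_ENCOUNTER_OTHER: (272, 4_053, 14, (10, 18.5)),
                ActivityGroup.HOME_BASED_CARE: (0, 0, 8, (5, 15)),
                ActivityGroup.TRAVEL: (637, 10_323, 14, (8, 20)),
            }
        ),
    }
)

#: Counts of unsuccessful visits by reason over the observation period.
FAILURE_COUNTS = MappingProxyType(
    {
        CLINIC_1: MappingProxyType(
            {
                VisitOutcome.PATIENT_UNAVAILABLE: 18,
                VisitOutcome.WRONG_ADDRESS: 2,
                VisitOutcome.DECEASED: 3,
                VisitOutcome.RELOCATED: 1,
                VisitOutcome.DOOR_LOCKED: 0,
                VisitOutcome.REFUSED_CARE: 0,
                VisitOutcome.UNKNOWN_PATIENT: 2,
            }
        ),
        CLINIC_2: MappingProxyType(
            {
                VisitOutcome.PATIENT_UNAVAILABLE: 89,
                VisitOutcome.WRONG_ADDRESS: 43,
                VisitOutcome.DECEASED: 0,
                VisitOutcome.RELOCATED: 1,
                VisitOutcome.DOOR_LOCKED: 10,
                VisitOutcome.REFUSED_CARE: 1,
                VisitOutcome.UNKNOWN_PATIENT: 21,
            }
        ),
    }
)

#: Per-visit success probabilities (successful / attempted).
P_SUCCESS = MappingProxyType({CLINIC_1: 0.973, CLINIC_2: 0.715})

#: Mean patients per successfully visited household.
PATIENTS_PER_HOUSEHOLD = MappingProxyType({CLINIC_1: 1.8, CLINIC_2: 1.2})

#: Shares of successful visits by care purpose (TB only / non-TB only / both).
PURPOSE_SHARES = MappingProxyType(
    {
        CLINIC_1: MappingProxyType(
            {
                VisitPurpose.TB_ONLY: 0.039,
                VisitPurpose.NON_TB_ONLY: 0.439,
                VisitPurpose.BOTH: 0.522,
            }
        ),
        CLINIC_2: MappingProxyType(
            {
                VisitPurpose.TB_ONLY: 0.032,
                VisitPurpose.NON_TB_ONLY: 0.941,
                VisitPurpose.BOTH: 0.027,
            }
        ),
    }
)

#: Annual cost totals by category (USD 2019), after annualization of capital
#: goods, as estimated bottom-up for each clinic.  Building space is a single
#: shared resource whose annual value splits equally between the clinics
#: (32.46 each).
ANNUAL_COST_TOTALS_USD = MappingProxyType(
    {
        CLINIC_1: MappingProxyType(
            {
                "equipment": Decimal("2880"),
                "staff": Decimal("54943"),
                "consumables": Decimal("3972"),
                "overhead": Decimal("7496"),
                "implementation": Decimal("2457"),
                "building": Decimal("32.46"),
            }
        ),
        CLINIC_2: MappingProxyType(
            {
                "equipment": Decimal("1766"),
                "staff": Decimal("37502"),
                "consumables": Decimal("2270"),
                "overhead": Decimal("5434"),
                "implementation": Decimal("2093"),
                "building": Decimal("32.46"),
            }
        ),
    }
)

#: Observation window of the field study.
STUDY_MONTHS_OBSERVED = 8
STUDY_START = "2018-03-01"
STUDY_END = "2018-10-31"
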