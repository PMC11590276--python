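"""Domain types shared across the pipeline.

Conventions
-----------
* CKD stages are the strings ``"1" "2" "3a" "3b" "4" "5"``; absence of CKD
  is ``"none"``. :data:`STAGE_SEVERITY` orders them by severity.
* Dates are :class:`datetime.date`; intervals carry inclusive endpoints.
* Cost components are the seven government-perspective categories reported
  for CKD: emergency, non-dialysis hospital, medication, primary care,
  community pathology, dialysis and renal outpatient services.
* Money in ledgers is float AUD (2023 dollars), always an exact multiple of
  one cent; the costing primitives compute in integer cents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional

# ---------------------------------------------------------------------------
# Closed vocabularies

STAGES = ("1", "2", "3a", "3b", "4", "5")
STAGES_WITH_NONE = ("none",) + STAGES

#: severity rank; higher = more severe. "none" ranks below every CKD stage.
STAGE_SEVERITY = {s: i for i, s in enumerate(STAGES_WITH_NONE)}

SEXES = ("male", "female")
REMOTENESS = ("major_cities", "regional", "remote")

#: 5-year age bands, 18+ cohort (18-19 folded into the 15-19 band's upper half).
AGE_BANDS = (
    "18-24", "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85-89", "90+",
)

#: numeric age attached to a band for eGFR computation (band midpoint).
AGE_BAND_MIDPOINT = {
    "18-24": 21.0, "25-29": 27.0, "30-34": 32.0, "35-39": 37.0,
    "40-44": 42.0, "45-49": 47.0, "50-54": 52.0, "55-59": 57.0,
    "60-64": 62.0, "65-69": 67.0, "70-74": 72.0, "75-79": 77.0,
    "80-84": 82.0, "85-89": 87.0, "90+": 92.0,
}

COMPONENTS = (
    "emergency",
    "hospital_nondialysis",
    "medication",
    "primary_care",
    "pathology",
    "dialysis",
    "outpatient",
)

ANALYTES = ("creatinine", "uacr", "hba1c", "fpg", "other")

EVENT_KINDS = (
    "admission", "emergency", "prescription", "gp_visit", "pathology_collection",
)

EMERGENCY_END_STATUSES = ("admitted", "discharged", "died", "left_at_own_risk")


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class PersonRecord:
    """Demographics and matching covariates for one individual."""

    person_id: str
    sex: str
    age_band: str
    indigenous: bool
    remoteness: str
    diabetes: bool
    death_date: Optional[date] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.remoteness not in REMOTENESS:
            raise ValueError(f"unknown remoteness {self.remoteness!r}")

    @property
    def age_midpoint(self) -> float:
        return AGE_BAND_MIDPOINT[self.age_band]


@dataclass(frozen=True)
class LabResult:
    """One dated pathology measurement.

    ``value`` units: creatinine µmol/L, uACR mg/mmol, HbA1c %, fasting
    plasma glucose mmol/L.
    """

    person_id: str
    date: date
    analyte: str
    value: float
    provider_id: str = ""

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if not self.value > 0:
            raise ValueError("lab value must be positive")


@dataclass(frozen=True)
class UtilisationEvent:
    """One healthcare utilisation event with kind-specific payload.

    Payload keys by kind:
      admission            drg_code:str, icd_codes:tuple[str,...]
      emergency            end_status:str
      prescription         medication_code:str, n_repeats:int
      gp_visit             item_codes:tuple[str,...]
      pathology_collection item_codes:tuple[str,...], provider_id:str
    """

    person_id: str
    date: date
    kind: str
    payload: dict = field(default_factory=dict)

    _REQUIRED = {
        "admission": ("drg_code", "icd_codes"),
        "emergency": ("end_status",),
        "prescription": ("medication_code", "n_repeats"),
        "gp_visit": ("item_codes",),
        "pathology_collection": ("item_codes", "provider_id"),
    }

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        missing = [k for k in self._REQUIRED[self.kind] if k not in self.payload]
        if missing:
            raise ValueError(f"{self.kind} payload missing {missing}")


@dataclass(frozen=True)
class StagePeriod:
    """A dated interval (inclusive endpoints) with a fixed CKD stage."""

    person_id: str
    stage: str
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"invalid stage {self.stage!r}")
        if self.start_date > self.end_date:
            raise ValueError("start_date after end_date")

    @property
    def days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def person_years(self) -> float:
        # 365-day year by convention; the analysis year (2019) is not a leap year
        return self.days / 365.0


@dataclass(frozen=True)
class FollowUpWindow:
    """Per-person follow-up interval within the analysis year."""

    person_id: str
    start_date: date
    end_date: date
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    @property
    def days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass
class CostLedger:
    """Per-person component-wise monetary totals (2023 AUD) over a window."""

    person_id: str
    window: tuple[date, date]
    components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in COMPONENTS:
            self.components.setdefault(c, 0.0)
        extra = set(self.components) - set(COMPONENTS)
        if extra:
            raise ValueError(f"unknown components {sorted(extra)}")

    @property
    def total(self) -> float:
        return sum(self.components.values())

    def scaled(self, factor: float) -> "CostLedger":
        return CostLedger(
            person_id=self.person_id,
            window=self.window,
            components={c: round(v * factor, 2) for c, v in self.components.items()},
        )


# ---------------------------------------------------------------------------
# Matching


@dataclass(frozen=True)
class MatchKey:
    """Exact-matching covariates: 5-year age band, sex, indigenous status,
    remoteness and evidence of diabetes."""

    age_band: str
    sex: str
    indigenous: bool
    remoteness: str
    diabetes: bool


RELAXATION_LEVELS = (
    "none",
    "remoteness",
    "remoteness+sex",
    "remoteness+sex+indigenous",
    "unmatched",
)


@dataclass(frozen=True)
class MatchedPair:
    case_id: str
    control_id: Optional[str]
    relaxation_level: str
    case_followup_days: int

    def __post_init__(self) -> None:
        if self.relaxation_level not in RELAXATION_LEVELS:
            raise ValueError(f"bad relaxation level {self.relaxation_level!r}")
        if (self.control_id is None) != (self.relaxation_level == "unmatched"):
            raise ValueError("control_id must be absent iff unmatched")
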