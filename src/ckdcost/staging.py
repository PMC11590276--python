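"""Longitudinal CKD identification and KDIGO staging from dated labs.

CKD is confirmed by chronicity: two qualifying results strictly more than
90 days apart with every same-analyte result inside that window also
qualifying.  Qualifying means eGFR < 60 mL/min/1.73m² (creatinine
pathway) or sex-specific albuminuria (uACR ≥ 2.5 mg/mmol male,
≥ 3.5 mg/mmol female).  The confirmation date is the second test of the
earliest qualifying pair.

Stage history is a ratchet: the stage at any date is the most severe stage
confirmed at or before that date; improvement in later labs never lowers
the stage.  A creatinine confirmatory pair whose two endpoint eGFRs imply
different stages contributes the least severe of the two.  Any hospital
dialysis code (ICD Z49) forces Stage 5 from its date.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

from .types import (
    FollowUpWindow,
    LabResult,
    PersonRecord,
    STAGE_SEVERITY,
    StagePeriod,
)

EGFR_CKD_THRESHOLD = 60.0
UACR_THRESHOLD_MALE = 2.5
UACR_THRESHOLD_FEMALE = 3.5
CHRONICITY_DAYS = 90  # strictly greater-than

DIALYSIS_ICD_PREFIX = "Z49"


class UnstageableError(ValueError):
    """CKD confirmed via uACR but no eGFR available to assign a stage."""


@dataclass(frozen=True)
class EgfrResult:
    person_id: str
    date: date
    egfr: float

    def __post_init__(self) -> None:
        if not self.egfr > 0:
            raise ValueError("egfr must be positive")


@dataclass(frozen=True)
class AlbuminuriaResult:
    person_id: str
    date: date
    uacr: float
    positive: bool


# ---------------------------------------------------------------------------
# eGFR


def compute_egfr(creatinine_umol_l: float, age: float, sex: str) -> float:
    """Estimated GFR (mL/min/1.73m²) from serum creatinine via CKD-EPI 2009.

    The race-free form of the 2009 creatinine equation, as used in
    Australian laboratory reporting; creatinine in µmol/L is converted to
    mg/dL by dividing by 88.4.

    Parameters
    ----------
    creatinine_umol_l : serum creatinine, µmol/L (> 0)
    age : age in years (≥ 18 for the adult equation)
    sex : ``"male"`` or ``"female"``
    """
    if not creatinine_umol_l > 0:
        raise ValueError("creatinine must be positive")
    scr = creatinine_umol_l / 88.4  # mg/dL
    if sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    elif sex == "male":
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    else:
        raise ValueError(f"unknown sex {sex!r}")
    ratio = scr / kappa
    egfr = (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993**age
        * sex_factor
    )
    return egfr


def albuminuria_positive(uacr: float, sex: str) -> bool:
    """Sex-specific albuminuria rule: uACR ≥ 2.5 (male) / ≥ 3.5 (female) mg/mmol."""
    threshold = UACR_THRESHOLD_MALE if sex == "male" else UACR_THRESHOLD_FEMALE
    return uacr >= threshold


def derive_egfr_series(
    labs: Iterable[LabResult], age: float, sex: str
) -> list[EgfrResult]:
    """Sorted eGFR series from the creatinine results in ``labs``."""
    out = [
        EgfrResult(l.person_id, l.date, compute_egfr(l.value, age, sex))
        for l in labs
        if l.analyte == "creatinine"
    ]
    out.sort(key=lambda r: (r.date, r.egfr))
    return out


def derive_albuminuria_series(
    labs: Iterable[LabResult], sex: str
) -> list[AlbuminuriaResult]:
    """Sorted albuminuria series from the uACR results in ``labs``."""
    out = [
        AlbuminuriaResult(l.person_id, l.date, l.value, albuminuria_positive(l.value, sex))
        for l in labs
        if l.analyte == "uacr"
    ]
    out.sort(key=lambda r: (r.date, r.uacr))
    return out


# ---------------------------------------------------------------------------
# Chronicity windows

def _confirmations(
    dated_values: Sequence[tuple[date, float]], qualifies, first_only: bool = False
) -> list[tuple[date, list[float], list[tuple[date, float]]]]:
    """Scan a sorted same-analyte series for chronicity confirmations.

    Returns one entry per date that closes a qualifying pair: the date,
    its values, and the earlier run members strictly more than 90 days
    before it (candidate pair openers).  A run is a maximal streak of
    consecutive all-qualifying dates; any non-qualifying result inside a
    window — including one on the same date as an endpoint — breaks the
    window, per the "all other tests within this window" rule.
    """
    confirmations: list[tuple[date, list[float], list[tuple[date, float]]]] = []
    run: list[tuple[date, list[float]]] = []
    for d, group in itertools.groupby(dated_values, key=lambda t: t[0]):
        vs = [v for _, v in group]
        if all(qualifies(v) for v in vs):
            openers = [
                (d0, v0)
                for d0, vs0 in run
                for v0 in vs0
                if (d - d0).days > CHRONICITY_DAYS
            ]
            if openers:
                confirmations.append((d, vs, openers))
                if first_only:
                    return confirmations
            run.append((d, vs))
        else:
            run = []
    return confirmations


def _check_sorted(dates: Sequence[date]) -> None:
    for a, b in zip(dates, dates[1:]):
        if b < a:
            raise ValueError("input labs must be sorted by date")


def detect_ckd(
    labs: Sequence[LabResult], sex: str, age: float
) -> Optional[date]:
    """Date CKD is first confirmed by either chronicity criterion, else None.

    ``labs`` must be sorted by date.  The creatinine criterion needs two
    eGFR < 60 results strictly more than 90 days apart with every eGFR test
    inside the window also < 60; the uACR criterion is analogous with the
    sex-specific albuminuria cutoff.  The confirmation date is the second
    test of the earliest qualifying pair.
    """
    _check_sorted([l.date for l in labs])
    dates: list[date] = []

    egfr = derive_egfr_series(labs, age, sex)
    hits = _confirmations(
        [(r.date, r.egfr) for r in egfr],
        lambda v: v < EGFR_CKD_THRESHOLD,
        first_only=True,
    )
    if hits:
        dates.append(hits[0][0])

    alb = derive_albuminuria_series(labs, sex)
    hits = _confirmations(
        [(r.date, r.uacr) for r in alb],
        lambda v: albuminuria_positive(v, sex),
        first_only=True,
    )
    if hits:
        dates.append(hits[0][0])

    return min(dates) if dates else None


# ---------------------------------------------------------------------------
# KDIGO stage assignment


def assign_kdigo_stage(egfr: float, albuminuria_pos: bool) -> Optional[str]:
    """KDIGO stage from an eGFR value and albuminuria status.

    Stages 1 and 2 require albuminuria (eGFR alone ≥ 60 is not CKD);
    stages 3a-5 are defined by eGFR bands regardless of albuminuria.
    """
    if not egfr > 0:
        raise ValueError("egfr must be positive")
    if egfr >= 90:
        return "1" if albuminuria_pos else None
    if egfr >= 60:
        return "2" if albuminuria_pos else None
    if egfr >= 45:
        return "3a"
    if egfr >= 30:
        return "3b"
    if egfr >= 15:
        return "4"
    return "5"


def _stage_confirmation_events(
    labs: Sequence[LabResult],
    dialysis_dates: Sequence[date],
    sex: str,
    age: float,
) -> list[tuple[date, str]]:
    """All (date, stage) stage-confirmation events for one person.

    Creatinine pathway: every test closing a qualifying sub-60 window
    confirms, at its date, the least severe of the pair's two endpoint
    stages; among available openers the one giving the most severe pair
    stage is used (the ratchet keeps the running maximum anyway).
    uACR pathway: a closing albuminuria window confirms the KDIGO stage
    implied by the most recent eGFR on or before the confirmation date.
    Dialysis (Z49) events confirm Stage 5 at their date.
    """
    events: list[tuple[date, str]] = []

    egfr = derive_egfr_series(labs, age, sex)
    for d, vs, openers in _confirmations(
        [(r.date, r.egfr) for r in egfr], lambda v: v < EGFR_CKD_THRESHOLD
    ):
        sev_close = max(STAGE_SEVERITY[assign_kdigo_stage(v, False)] for v in vs)
        best = max(STAGE_SEVERITY[assign_kdigo_stage(v0, False)] for _, v0 in openers)
        pair_sev = min(sev_close, best)
        stage = next(s for s, r in STAGE_SEVERITY.items() if r == pair_sev)
        events.append((d, stage))

    alb = derive_albuminuria_series(labs, sex)
    for d, _, _ in _confirmations(
        [(r.date, r.uacr) for r in alb], lambda v: albuminuria_positive(v, sex)
    ):
        prior = [r for r in egfr if r.date <= d]
        if not prior:
            raise UnstageableError(
                "uACR-confirmed CKD but no eGFR on or before confirmation date"
            )
        stage = assign_kdigo_stage(prior[-1].egfr, True)
        events.append((d, stage))

    for d in dialysis_dates:
        events.append((d, "5"))

    events.sort(key=lambda e: (e[0], STAGE_SEVERITY[e[1]]))
    return events


def build_stage_history(
    labs: Sequence[LabResult],
    dialysis_dates: Sequence[date],
    followup: FollowUpWindow,
    sex: str,
    age: float,
) -> list[StagePeriod]:
    """Build the person's stage periods over the follow-up window.

    The returned periods partition [max(first confirmation, window start),
    window end] with inclusive endpoints; severity never decreases; the day
    a more severe stage is confirmed starts the new period.  Returns []
    when no CKD is confirmed on or before the window end.
    """
    if followup.excluded:
        return []
    labs = sorted(labs, key=lambda l: (l.date, l.analyte, l.value))
    events = _stage_confirmation_events(labs, sorted(dialysis_dates), sex, age)

    # ratchet breakpoints: dates where the running maximum severity increases
    breakpoints: list[tuple[date, str]] = []
    current = 0
    for d, stage in events:
        sev = STAGE_SEVERITY[stage]
        if sev > current:
            current = sev
            breakpoints.append((d, stage))

    breakpoints = [(d, s) for d, s in breakpoints if d <= followup.end_date]
    if not breakpoints:
        return []

    start = max(breakpoints[0][0], followup.start_date)
    # stage in force at `start`
    in_force = [s for d, s in breakpoints if d <= start]
    upcoming = [(d, s) for d, s in breakpoints if d > start]

    periods: list[StagePeriod] = []
    cur_stage = in_force[-1]
    cur_start = start
    for d, s in upcoming:
        periods.append(StagePeriod(followup.person_id, cur_stage, cur_start, d - timedelta(days=1)))
        cur_stage, cur_start = s, d
    periods.append(StagePeriod(followup.person_id, cur_stage, cur_start, followup.end_date))
    return periods


# ---------------------------------------------------------------------------
# Follow-up and diabetes


def resolve_followup(
    person: PersonRecord, record_dates: Iterable[date], year: int
) -> FollowUpWindow:
    """Follow-up window for the analysis year, with loss-to-follow-up exclusion.

    A person is excluded when they have no pathology, hospital, emergency
    or mortality record dated in the analysis year or after it.  Death in
    the year truncates the window at the death date.
    """
    year_start, year_end = date(year, 1, 1), date(year, 12, 31)
    dates = list(record_dates)
    if person.death_date is not None:
        dates.append(person.death_date)
    if not any(d >= year_start for d in dates):
        return FollowUpWindow(
            person.person_id, year_start, year_end,
            excluded=True, exclusion_reason="lost_to_follow_up",
        )
    end = year_end
    if person.death_date is not None and year_start <= person.death_date <= year_end:
        end = person.death_date
    return FollowUpWindow(person.person_id, year_start, end)


def derive_diabetes_flag(labs: Iterable[LabResult]) -> bool:
    """Evidence of diabetes: two separate HbA1c > 6.5 % or two separate
    fasting plasma glucose results > 7.0 mmol/L (distinct dates)."""
    labs = list(labs)
    hba1c_dates = {l.date for l in labs if l.analyte == "hba1c" and l.value > 6.5}
    if len(hba1c_dates) >= 2:
        return True
    fpg_dates = {l.date for l in labs if l.analyte == "fpg" and l.value > 7.0}
    return len(fpg_dates) >= 2
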