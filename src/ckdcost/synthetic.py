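"""Synthetic linked administrative records with the structure the analysis assumes.

The generator emulates a state-wide linked repository: demographics,
dated pathology (creatinine, uACR, HbA1c, fasting glucose), hospital
separations with AR-DRG codes and dialysis ICD flags, emergency
presentations, prescriptions and GP billing, plus a unit-cost catalogue
and population stratum counts.  True CKD stage is assigned first and the
lab trajectory is built backward from it: a confirmatory pair 91-365 days
apart inside the stage's eGFR (or uACR) band, interim results consistent
with the chronicity rule, so the staging module recovers the assigned
stage by construction.  A configurable fraction of trajectories carry an
inconsistent interim result to exercise the rejection path.

Annual component costs are drawn from a zero-inflated gamma (point mass
at zero, gamma above it — the positive skew the downstream gamma/log-link
model family assumes); the configured mean is the unconditional mean.
Event counts are the target cost divided by the unit price with
stochastic rounding, so expected priced cost equals the drawn target
despite discrete event prices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .costing import CostCatalog, cost_pathology_collection, price_medication
from ._money import to_cents, to_aud, scale_cents
from .types import (
    AGE_BANDS,
    AGE_BAND_MIDPOINT,
    LabResult,
    PersonRecord,
    REMOTENESS,
    STAGES_WITH_NONE,
    UtilisationEvent,
)

# ---------------------------------------------------------------------------
# Default study conditions

#: share of CKD in the cohort and its split across stages, following the
#: relative stage mix of the observed cohort (Stage 3a dominant, Stages 1-2
#: scarce because uACR testing is required to diagnose them).
DEFAULT_STAGE_PREVALENCE = {
    "none": 0.900,
    "1": 0.0068,
    "2": 0.0075,
    "3a": 0.0543,
    "3b": 0.0217,
    "4": 0.0064,
    "5": 0.0033,
}

DEFAULT_DIABETES_PROB = {
    "none": 0.08, "1": 0.44, "2": 0.49, "3a": 0.12, "3b": 0.15, "4": 0.20, "5": 0.15,
}

#: annual unconditional mean (2023 AUD) and gamma shape per component/stage;
#: CKD-stage means = non-CKD baseline + the stage's attributable increment.
DEFAULT_COST_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "emergency": {
        "none": (300, 1.2), "1": (448, 1.2), "2": (555, 1.2), "3a": (569, 1.2),
        "3b": (850, 1.2), "4": (1328, 1.2), "5": (2754, 1.2),
    },
    "hospital_nondialysis": {
        "none": (1500, 0.8), "1": (3015, 0.8), "2": (3755, 0.8), "3a": (3970, 0.8),
        "3b": (6092, 0.8), "4": (9900, 0.8), "5": (21223, 0.8),
    },
    "medication": {
        "none": (600, 1.5), "1": (1974, 1.5), "2": (1772, 1.5), "3a": (1177, 1.5),
        "3b": (1431, 1.5), "4": (1721, 1.5), "5": (2380, 1.5),
    },
    "primary_care": {
        "none": (400, 1.5), "1": (715, 1.5), "2": (801, 1.5), "3a": (630, 1.5),
        "3b": (747, 1.5), "4": (863, 1.5), "5": (874, 1.5),
    },
    "pathology": {
        "none": (100, 1.5), "1": (114, 1.5), "2": (131, 1.5), "3a": (147, 1.5),
        "3b": (196, 1.5), "4": (268, 1.5), "5": (303, 1.5),
    },
    "dialysis": {
        "none": (0, 1.0), "1": (0, 1.0), "2": (0, 1.0), "3a": (0, 1.0),
        "3b": (0, 1.0), "4": (0, 1.0), "5": (26982, 1.0),
    },
}

DEFAULT_ZERO_COST_PROB = {
    "emergency": 0.75,
    "hospital_nondialysis": 0.70,
    "medication": 0.15,
    "primary_care": 0.10,
    "pathology": 0.20,
    "dialysis": 0.35,
}

#: per-person-year top-down outpatient allocation rates by stage (renal
#: clinics; zero in Stages 1-2 where nephrology referral is uncommon)
DEFAULT_OUTPATIENT_PPY = {
    "1": 0.0, "2": 0.0, "3a": 15.0, "3b": 156.0, "4": 274.0, "5": 942.0,
}

#: per-person-year home-based dialysis allocation, Stage 5 only (top-down)
DEFAULT_HOME_DIALYSIS_PPY = 10000.0

_SEX_MALE_PROB = {
    "none": 0.49, "1": 0.60, "2": 0.66, "3a": 0.46, "3b": 0.45, "4": 0.49, "5": 0.59,
}
_REMOTENESS_PROB = {
    "none": (0.78, 0.16, 0.06),
    "1": (0.55, 0.16, 0.29),
    "2": (0.66, 0.17, 0.17),
    "3a": (0.76, 0.20, 0.04),
    "3b": (0.76, 0.19, 0.05),
    "4": (0.75, 0.19, 0.06),
    "5": (0.69, 0.17, 0.14),
}
_INDIGENOUS_PROB = {
    "none": 0.03, "1": 0.32, "2": 0.18, "3a": 0.02, "3b": 0.03, "4": 0.05, "5": 0.19,
}
_AGE_GROUPS = {
    "<50": AGE_BANDS[0:7],
    "50s": ("50-54", "55-59"),
    "60s": ("60-64", "65-69"),
    "70s": ("70-74", "75-79"),
    "80s": ("80-84", "85-89"),
    "90+": ("90+",),
}
_AGE_GROUP_PROB = {
    "none": (0.50, 0.15, 0.13, 0.12, 0.07, 0.03),
    "1": (0.39, 0.29, 0.25, 0.07, 0.00, 0.00),
    "2": (0.09, 0.16, 0.29, 0.32, 0.13, 0.01),
    "3a": (0.02, 0.04, 0.15, 0.35, 0.34, 0.10),
    "3b": (0.02, 0.03, 0.09, 0.26, 0.41, 0.19),
    "4": (0.05, 0.05, 0.10, 0.22, 0.37, 0.21),
    "5": (0.19, 0.20, 0.23, 0.21, 0.14, 0.03),
}

#: eGFR sampling band per true stage (kept clear of KDIGO boundaries)
_EGFR_BAND = {
    "none": (70.0, 110.0),
    "1": (92.0, 115.0),
    "2": (63.0, 87.0),
    "3a": (46.0, 58.0),
    "3b": (31.0, 43.0),
    "4": (16.0, 28.0),
    "5": (5.0, 13.0),
}

PATHOLOGY_PROVIDERS = ("WDP", "PWEST", "CLIN", "ACL")
MAIN_PATHOLOGY_PROVIDER = "WDP"
DIALYSIS_DRG = "L61Z"


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort."""

    n_persons: int = 10_000
    analysis_year: int = 2019
    stage_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PREVALENCE))
    diabetes_prob_by_stage: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIABETES_PROB))
    uacr_testing_prob: float = 0.24
    component_cost_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_COST_PARAMS.items()})
    zero_cost_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZERO_COST_PROB))
    death_prob: float = 0.02
    ltfu_prob: float = 0.02
    inconsistent_interim_frac: float = 0.05
    gp_extract_prob: float = 0.25
    main_provider_prob: float = 0.70
    outpatient_ppy_by_stage: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTPATIENT_PPY))
    home_dialysis_ppy: float = DEFAULT_HOME_DIALYSIS_PPY
    local_pop_multiplier: float = 20.0
    national_multiplier: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.uacr_testing_prob, self.death_prob, self.ltfu_prob,
            self.inconsistent_interim_frac, self.gp_extract_prob,
            self.main_provider_prob,
            *self.stage_prevalence.values(),
            *self.diabetes_prob_by_stage.values(),
            *self.zero_cost_prob.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if set(self.stage_prevalence) != set(STAGES_WITH_NONE):
            raise ValueError("stage_prevalence must cover none + six stages")
        if abs(sum(self.stage_prevalence.values()) - 1.0) > 1e-9:
            raise ValueError("stage_prevalence must sum to 1")
        for comp, by_stage in self.component_cost_params.items():
            for stage, (mean, shape) in by_stage.items():
                if mean < 0 or (mean > 0 and shape <= 0):
                    raise ValueError(
                        f"invalid cost params for {comp}/{stage}: mean {mean}, shape {shape}"
                    )
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")


# ---------------------------------------------------------------------------
# eGFR inversion (trajectories are built backward from the target stage)


def invert_egfr(target_egfr: float, age: float, sex: str) -> float:
    """Serum creatinine (µmol/L) whose CKD-EPI 2009 eGFR equals the target."""
    if not target_egfr > 0:
        raise ValueError("target eGFR must be positive")
    if sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    elif sex == "male":
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    else:
        raise ValueError(f"unknown sex {sex!r}")
    base = 141.0 * 0.993**age * sex_factor
    ratio = target_egfr / base
    if ratio < 1.0:  # creatinine above kappa
        scr = kappa * ratio ** (-1.0 / 1.209)
    else:
        scr = kappa * ratio ** (1.0 / alpha)
    return scr * 88.4


# ---------------------------------------------------------------------------
# Cost catalogue


def generate_cost_catalog(config: SimConfig) -> CostCatalog:
    """Unit-cost catalogue covering every code the generator emits.

    Prices are fixed plausible 2019 AUD amounts (hence deterministic for a
    given config); the inflation index takes them to 2023 AUD.
    """
    return CostCatalog(
        drg_unit_costs={
            "F62B": 5500.00,   # heart failure
            "K60A": 2800.00,   # diabetes-related admission
            "E65A": 17000.00,  # complex respiratory/renal
            DIALYSIS_DRG: 520.00,  # same-day dialysis session
        },
        dialysis_drgs=frozenset({DIALYSIS_DRG}),
        emergency_costs={
            "admitted": 1050.00,
            "discharged": 580.00,
            "died": 1900.00,
            "left_at_own_risk": 310.00,
        },
        mbs_item_fees={
            # GP attendances
            "23": 38.75, "36": 75.05,
            # pathology items
            "66500": 9.70, "66512": 17.70, "65070": 16.95,
            "66536": 15.65, "66605": 24.25,
        },
        collection_fee=6.75,
        bulk_billing_fee=6.60,
        medication_tier_prices={
            "statin": {"general": 31.60, "concessional": 7.40, "safety_net": 0.0},
            "ace_inhibitor": {"general": 22.40, "concessional": 7.40, "safety_net": 0.0},
            "arb": {"general": 28.90, "concessional": 7.40, "safety_net": 0.0},
            "sglt2": {"general": 58.80, "concessional": 7.40, "safety_net": 0.0},
        },
        medication_tier_weights={
            "statin": {"general": 0.35, "concessional": 0.50, "safety_net": 0.15},
            "ace_inhibitor": {"general": 0.30, "concessional": 0.55, "safety_net": 0.15},
            "arb": {"general": 0.30, "concessional": 0.55, "safety_net": 0.15},
            "sglt2": {"general": 0.40, "concessional": 0.50, "safety_net": 0.10},
        },
        dispensing_fee=7.74,
        handling_fee=1.08,
        safety_net_recording_fee=1.31,
        inflation_index={2019: 1.16, 2023: 1.0},
        cost_year=2019,
    )


# ---------------------------------------------------------------------------
# Cohort generation

_GP_ITEMS = (("23",), ("36",))
_GP_ITEM_PROBS = (0.8, 0.2)
_PATH_PANELS = (
    ("66500", "66512", "65070"),                      # UEC + FBC + lipids
    ("66500", "66512", "65070", "66536", "66605"),    # broad chronic-disease panel
)
_PATH_PANEL_PROBS = (0.7, 0.3)
_ED_STATUSES = ("admitted", "discharged", "left_at_own_risk")
_ED_STATUS_PROBS = (0.40, 0.55, 0.05)
_MEDICATIONS = ("statin", "ace_inhibitor", "arb", "sglt2")
_MED_PROBS = (0.35, 0.25, 0.25, 0.15)
_NONDIALYSIS_DRGS = ("F62B", "K60A", "E65A")
_DRG_PROBS = (0.45, 0.35, 0.20)


def _stoch_round(x: float, rng: np.random.Generator) -> int:
    """floor(x) + Bernoulli(frac(x)): integer with expectation exactly x."""
    f = math.floor(x)
    return f + int(rng.random() < (x - f))


def _choice(rng: np.random.Generator, options, probs) -> object:
    return options[int(rng.choice(len(options), p=np.asarray(probs, dtype=float)))]


def _draw_annual_cost(
    mean: float, shape: float, zero_prob: float, rng: np.random.Generator
) -> float:
    """Zero-inflated gamma with unconditional mean ``mean``."""
    if mean <= 0:
        return 0.0
    if rng.random() < zero_prob:
        return 0.0
    cond_mean = mean / (1.0 - zero_prob)
    return float(rng.gamma(shape, cond_mean / shape))


def generate_cohort(
    config: SimConfig,
) -> tuple[list[PersonRecord], list[LabResult], list[UtilisationEvent], pd.DataFrame]:
    """Generate persons, labs, utilisation events and the per-person truth table.

    The truth table carries ``true_stage`` (the stage the trajectory was
    built for), ``detectable`` (False for designed-inconsistent
    trajectories, which the chronicity rule must reject), ``ltfu``,
    ``in_gp_extract`` and ``predominant_provider``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    catalog = generate_cost_catalog(config)
    year = config.analysis_year
    year_start = date(year, 1, 1)

    stage_labels = list(STAGES_WITH_NONE)
    stage_probs = np.array([config.stage_prevalence[s] for s in stage_labels])

    # 2023-AUD expected unit prices used to convert target costs to counts
    idx19 = catalog.inflation_index[catalog.cost_year]
    drg_price = {
        d: to_aud(scale_cents(to_cents(catalog.drg_unit_costs[d]), idx19))
        for d in catalog.drg_unit_costs
    }
    ed_price = {
        s: to_aud(scale_cents(to_cents(catalog.emergency_costs[s]), idx19))
        for s in _ED_STATUSES
    }
    ed_mean_price = float(np.dot([ed_price[s] for s in _ED_STATUSES], _ED_STATUS_PROBS))
    med_price = {m: price_medication(m, catalog) for m in _MEDICATIONS}
    med_mean_price = 1.5 * float(np.dot([med_price[m] for m in _MEDICATIONS], _MED_PROBS))
    gp_mean_price = float(
        np.dot([catalog.mbs_item_fees[i[0]] * idx19 for i in _GP_ITEMS], _GP_ITEM_PROBS)
    )
    panel_price = [cost_pathology_collection(p, catalog) for p in _PATH_PANELS]
    panel_mean_price = float(np.dot(panel_price, _PATH_PANEL_PROBS))

    persons: list[PersonRecord] = []
    labs: list[LabResult] = []
    events: list[UtilisationEvent] = []
    truth_rows: list[dict] = []

    for i in range(config.n_persons):
        pid = f"P{i:06d}"
        true_stage = str(_choice(rng, stage_labels, stage_probs))
        sex = "male" if rng.random() < _SEX_MALE_PROB[true_stage] else "female"
        remoteness = str(_choice(rng, REMOTENESS, _REMOTENESS_PROB[true_stage]))
        indigenous = bool(rng.random() < _INDIGENOUS_PROB[true_stage])
        group = str(_choice(rng, list(_AGE_GROUPS), _AGE_GROUP_PROB[true_stage]))
        age_band = str(_choice(
            rng, _AGE_GROUPS[group], [1 / len(_AGE_GROUPS[group])] * len(_AGE_GROUPS[group])
        ))
        age = AGE_BAND_MIDPOINT[age_band]
        diabetes = bool(rng.random() < config.diabetes_prob_by_stage[true_stage])
        ltfu = bool(rng.random() < config.ltfu_prob)
        dies = (not ltfu) and bool(rng.random() < config.death_prob)
        death_day = int(rng.integers(30, 365)) if dies else None  # day-of-year, 1-based
        death_date = year_start + timedelta(days=death_day - 1) if dies else None
        followup_days = death_day if dies else 365
        inconsistent = (
            true_stage != "none"
            and bool(rng.random() < config.inconsistent_interim_frac)
        )
        in_gp_extract = bool(rng.random() < config.gp_extract_prob)
        provider = (
            MAIN_PATHOLOGY_PROVIDER
            if rng.random() < config.main_provider_prob
            else str(_choice(rng, PATHOLOGY_PROVIDERS[1:], [1 / 3] * 3))
        )

        person = PersonRecord(pid, sex, age_band, indigenous, remoteness,
                              diabetes, death_date)
        persons.append(person)

        _gen_labs(
            labs, rng, config, person, true_stage, age, inconsistent, ltfu,
            followup_days, provider,
        )
        if not ltfu:
            _gen_events(
                events, rng, config, person, true_stage, followup_days, provider,
                drg_price, ed_price, ed_mean_price, med_price, med_mean_price,
                gp_mean_price, panel_price, panel_mean_price,
                suppress_dialysis=inconsistent,
            )

        truth_rows.append(
            {
                "person_id": pid,
                "true_stage": true_stage,
                "detectable": (true_stage != "none") and not inconsistent and not ltfu,
                "ltfu": ltfu,
                "in_gp_extract": in_gp_extract,
                "predominant_provider": provider,
                "followup_days": 0 if ltfu else followup_days,
            }
        )

    labs.sort(key=lambda l: (l.person_id, l.date, l.analyte, l.value))
    events.sort(key=lambda e: (e.person_id, e.date, e.kind))
    truth = pd.DataFrame(truth_rows)
    return persons, labs, events, truth


def _rand_day(rng: np.random.Generator, start: date, end: date) -> date:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def _lab_provider(rng, predominant: str) -> str:
    if rng.random() < 0.98:
        return predominant
    others = [p for p in PATHOLOGY_PROVIDERS if p != predominant]
    return str(_choice(rng, others, [1 / len(others)] * len(others)))


def _gen_labs(
    labs, rng, config, person, true_stage, age, inconsistent, ltfu,
    followup_days, provider,
) -> None:
    """Build the person's lab trajectory backward from the true stage."""
    pid, sex = person.person_id, person.sex
    year = config.analysis_year
    year_start = date(year, 1, 1)
    fu_end = year_start + timedelta(days=followup_days - 1)
    lo, hi = _EGFR_BAND[true_stage]

    def egfr_lab(d: date, target: float) -> LabResult:
        return LabResult(pid, d, "creatinine", invert_egfr(target, age, sex),
                         _lab_provider(rng, provider))

    def uacr_lab(d: date, positive: bool) -> LabResult:
        thr = 2.5 if sex == "male" else 3.5
        val = (
            float(rng.uniform(thr + 1.0, thr + 25.0))
            if positive
            else float(rng.uniform(0.3, thr - 0.3))
        )
        return LabResult(pid, d, "uacr", val, _lab_provider(rng, provider))

    if ltfu:
        # only old records, none in or after the analysis year
        old = date(year - 3, 6, 1) + timedelta(days=int(rng.integers(0, 300)))
        labs.append(egfr_lab(old, float(rng.uniform(lo, hi))))
        return

    if true_stage == "none":
        n = int(rng.integers(1, 4))
        for _ in range(n):
            d = _rand_day(rng, date(year - 1, 1, 1), fu_end)
            labs.append(egfr_lab(d, float(rng.uniform(lo, hi))))
        if rng.random() < config.uacr_testing_prob:
            d = _rand_day(rng, date(year - 1, 1, 1), fu_end)
            labs.append(uacr_lab(d, positive=False))
    else:
        # confirmatory pair: second test 91-365 days after the first
        gap = int(rng.integers(91, 366))
        if rng.random() < 0.7 or followup_days < 240:
            d2 = _rand_day(rng, date(year - 1, 4, 1), date(year - 1, 12, 15))
        else:
            d2 = _rand_day(rng, year_start, year_start + timedelta(days=150))
        d1 = d2 - timedelta(days=gap)
        uacr_path = true_stage in ("1", "2")

        def band_val() -> float:
            return float(rng.uniform(lo, hi))

        if uacr_path:
            labs.append(uacr_lab(d1, positive=True))
            labs.append(uacr_lab(d2, positive=True))
            # eGFR context so the uACR confirmation is stageable
            labs.append(egfr_lab(d1, band_val()))
            labs.append(egfr_lab(d2, band_val()))
            if inconsistent:
                mid = d1 + timedelta(days=gap // 2)
                labs.append(uacr_lab(mid, positive=False))
            elif rng.random() < 0.5:
                mid = d1 + timedelta(days=gap // 2)
                labs.append(uacr_lab(mid, positive=True))
            # in-year maintenance results
            md = _rand_day(rng, max(year_start, d2), fu_end) if fu_end >= d2 else None
            if md is not None and md > d2:
                labs.append(egfr_lab(md, band_val()))
                labs.append(uacr_lab(md, positive=not inconsistent))
        else:
            labs.append(egfr_lab(d1, band_val()))
            labs.append(egfr_lab(d2, band_val()))
            if inconsistent:
                mid = d1 + timedelta(days=gap // 2)
                labs.append(egfr_lab(mid, 65.0 + float(rng.uniform(0, 20))))
            elif rng.random() < 0.5:
                mid = d1 + timedelta(days=gap // 2)
                labs.append(egfr_lab(mid, band_val()))
            md = _rand_day(rng, max(year_start, d2), fu_end) if fu_end >= d2 else None
            if md is not None and md > d2:
                # inconsistent persons get a non-qualifying maintenance result
                # so no later pair confirms either
                target = 65.0 + float(rng.uniform(0, 20)) if inconsistent else band_val()
                labs.append(egfr_lab(md, target))

    if person.diabetes:
        d_a = _rand_day(rng, date(year - 1, 1, 1), date(year - 1, 12, 31))
        d_b = _rand_day(rng, year_start, fu_end)
        for d in (d_a, d_b):
            labs.append(LabResult(pid, d, "hba1c", float(rng.uniform(6.8, 9.5)),
                                  _lab_provider(rng, provider)))
    elif rng.random() < 0.3:
        d = _rand_day(rng, year_start, fu_end)
        labs.append(LabResult(pid, d, "hba1c", float(rng.uniform(5.0, 6.0)),
                              _lab_provider(rng, provider)))


def _gen_events(
    events, rng, config, person, true_stage, followup_days, provider,
    drg_price, ed_price, ed_mean_price, med_price, med_mean_price,
    gp_mean_price, panel_price, panel_mean_price,
    suppress_dialysis: bool = False,
) -> None:
    pid = person.person_id
    year_start = date(config.analysis_year, 1, 1)
    fu_end = year_start + timedelta(days=followup_days - 1)
    frac = followup_days / 365.0

    def target(component: str) -> float:
        mean, shape = config.component_cost_params[component][true_stage]
        return frac * _draw_annual_cost(
            mean, shape, config.zero_cost_prob[component], rng
        )

    # hospital (non-dialysis)
    c = target("hospital_nondialysis")
    if c > 0:
        drg = str(_choice(rng, _NONDIALYSIS_DRGS, _DRG_PROBS))
        for _ in range(_stoch_round(c / drg_price[drg], rng)):
            events.append(UtilisationEvent(
                pid, _rand_day(rng, year_start, fu_end), "admission",
                {"drg_code": drg, "icd_codes": ("I10",)},
            ))

    # dialysis admissions (Z49-coded sessions); designed-inconsistent
    # trajectories get none, since a Z49 code would identify them regardless
    # of the lab chronicity rule
    c = 0.0 if suppress_dialysis else target("dialysis")
    if c > 0:
        for _ in range(_stoch_round(c / drg_price[DIALYSIS_DRG], rng)):
            events.append(UtilisationEvent(
                pid, _rand_day(rng, year_start, fu_end), "admission",
                {"drg_code": DIALYSIS_DRG, "icd_codes": ("Z49.1",)},
            ))

    # emergency
    c = target("emergency")
    if c > 0:
        for _ in range(_stoch_round(c / ed_mean_price, rng)):
            status = str(_choice(rng, _ED_STATUSES, _ED_STATUS_PROBS))
            events.append(UtilisationEvent(
                pid, _rand_day(rng, year_start, fu_end), "emergency",
                {"end_status": status},
            ))

    # prescriptions (repeats 0 or 1, equally likely)
    c = target("medication")
    if c > 0:
        for _ in range(_stoch_round(c / med_mean_price, rng)):
            med = str(_choice(rng, _MEDICATIONS, _MED_PROBS))
            events.append(UtilisationEvent(
                pid, _rand_day(rng, year_start, fu_end), "prescription",
                {"medication_code": med, "n_repeats": int(rng.integers(0, 2))},
            ))

    # GP visits
    c = target("primary_care")
    if c > 0:
        for _ in range(_stoch_round(c / gp_mean_price, rng)):
            items = tuple(_choice(rng, _GP_ITEMS, _GP_ITEM_PROBS))
            events.append(UtilisationEvent(
                pid, _rand_day(rng, year_start, fu_end), "gp_visit",
                {"item_codes": items},
            ))

    # community pathology collections
    c = target("pathology")
    if c > 0:
        for _ in range(_stoch_round(c / panel_mean_price, rng)):
            k = int(rng.choice(len(_PATH_PANELS), p=np.asarray(_PATH_PANEL_PROBS)))
            events.append(UtilisationEvent(
                pid, _rand_day(rng, year_start, fu_end), "pathology_collection",
                {"item_codes": tuple(_PATH_PANELS[k]),
                 "provider_id": _lab_provider(rng, provider)},
            ))


# ---------------------------------------------------------------------------
# Population strata


def generate_population_strata(
    config: SimConfig, case_counts: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Local and national population counts per stage × demographic stratum.

    ``case_counts`` carries columns stage, sex, indigenous, age_band,
    remoteness, cases.  The local population of a stratum is its case
    count scaled by ``local_pop_multiplier`` (the cohort is a sample of
    the jurisdiction); the national population is the local population
    scaled by ``national_multiplier``.
    """
    local = case_counts.copy()
    local["population"] = np.maximum(
        local["cases"],
        np.round(local["cases"] * config.local_pop_multiplier),
    ).astype(int)
    national = local[
        ["stage", "sex", "indigenous", "age_band", "remoteness"]
    ].copy()
    national["population"] = np.round(
        local["population"] * config.national_multiplier
    ).astype(int)
    return local.drop(columns=["cases"]), national


# ---------------------------------------------------------------------------
# Table output


def to_frames(
    persons: list[PersonRecord],
    labs: list[LabResult],
    events: list[UtilisationEvent],
) -> dict[str, pd.DataFrame]:
    """Flatten generated records into the fixed delimited-table layout."""
    frames: dict[str, pd.DataFrame] = {}
    frames["persons"] = pd.DataFrame(
        [
            {
                "person_id": p.person_id, "sex": p.sex, "age_band": p.age_band,
                "indigenous": p.indigenous, "remoteness": p.remoteness,
                "diabetes": p.diabetes,
                "death_date": p.death_date.isoformat() if p.death_date else "",
            }
            for p in persons
        ]
    )
    frames["labs"] = pd.DataFrame(
        [
            {
                "person_id": l.person_id, "date": l.date.isoformat(),
                "analyte": l.analyte, "value": l.value,
                "provider_id": l.provider_id,
            }
            for l in labs
        ]
    )
    rows_by_kind: dict[str, list[dict]] = {
        "admissions": [], "emergency": [], "prescriptions": [],
        "gp_billing": [], "pathology_collections": [],
    }
    for e in events:
        base = {"person_id": e.person_id, "date": e.date.isoformat()}
        if e.kind == "admission":
            rows_by_kind["admissions"].append(
                base | {"drg_code": e.payload["drg_code"],
                        "icd_codes": ";".join(e.payload["icd_codes"])})
        elif e.kind == "emergency":
            rows_by_kind["emergency"].append(
                base | {"end_status": e.payload["end_status"]})
        elif e.kind == "prescription":
            rows_by_kind["prescriptions"].append(
                base | {"medication_code": e.payload["medication_code"],
                        "n_repeats": e.payload["n_repeats"]})
        elif e.kind == "gp_visit":
            rows_by_kind["gp_billing"].append(
                base | {"item_codes": ";".join(e.payload["item_codes"])})
        elif e.kind == "pathology_collection":
            rows_by_kind["pathology_collections"].append(
                base | {"item_codes": ";".join(e.payload["item_codes"]),
                        "provider_id": e.payload["provider_id"]})
    for name, rows in rows_by_kind.items():
        frames[name] = pd.DataFrame(rows)
    return frames


def write_tables(
    outdir: str | Path,
    config: SimConfig,
    persons: list[PersonRecord],
    labs: list[LabResult],
    events: list[UtilisationEvent],
    truth: Optional[pd.DataFrame] = None,
) -> None:
    """Write the generated records as CSV files plus the echoed config (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in to_frames(persons, labs, events).items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    if truth is not None:
        truth.to_csv(outdir / "truth.csv", index=False)
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=2, default=str))
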