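"""Undiagnosed early-stage CKD adjustment and national cost extrapolation.

Early-stage CKD (Stages 1-2) needs a uACR result to diagnose, and uACR
testing coverage is low, so diagnosed counts understate prevalence.  The
adjustment multiplies population survey albuminuria proportions (share of
the eGFR ≥ 90 population with albuminuria → Stage 1; share of the eGFR
60-89 population → Stage 2) by the persistence fraction — the proportion
whose albuminuria is still present beyond 90 days, the chronicity
requirement — to estimate true stage counts, and subtracts the diagnosed
counts to get undiagnosed counts.

National extrapolation is a stratified rate transfer: within each
stage × sex × indigenous × age-band × remoteness stratum, the local case
rate (cases / local population) is applied to the national population
count, and the resulting national case counts are costed at the stage's
attributable per-person cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

STRATUM_KEY = ["stage", "sex", "indigenous", "age_band", "remoteness"]


@dataclass(frozen=True)
class UndiagnosedParams:
    """Inputs to the undiagnosed early-stage estimate."""

    p_stage1: float  # proportion of eGFR ≥ 90 population with albuminuria
    p_stage2: float  # proportion of eGFR 60-89 population with albuminuria
    persistence: float  # proportion with albuminuria persisting > 90 days
    pop_egfr_ge90: int
    pop_egfr_60_89: int
    observed_stage1: int
    observed_stage2: int

    def __post_init__(self) -> None:
        for p in (self.p_stage1, self.p_stage2, self.persistence):
            if not 0 <= p <= 1:
                raise ValueError("proportions must be in [0, 1]")
        for c in (self.pop_egfr_ge90, self.pop_egfr_60_89,
                  self.observed_stage1, self.observed_stage2):
            if c < 0:
                raise ValueError("counts must be non-negative")


def estimate_undiagnosed(
    params: UndiagnosedParams,
) -> tuple[dict[str, int], dict[str, int]]:
    """Estimated true and undiagnosed Stage 1-2 counts.

    estimated_K = round(pop_K × p_K × persistence); the product is taken in
    full precision and rounded once, then the observed (diagnosed) count is
    subtracted.  A negative difference is floored at zero with a warning.
    """
    estimated = {
        "1": round(params.pop_egfr_ge90 * params.p_stage1 * params.persistence),
        "2": round(params.pop_egfr_60_89 * params.p_stage2 * params.persistence),
    }
    observed = {"1": params.observed_stage1, "2": params.observed_stage2}
    undiagnosed = {}
    for k in ("1", "2"):
        diff = estimated[k] - observed[k]
        if diff < 0:
            warnings.warn(
                f"estimated Stage {k} count below observed; flooring at 0",
                stacklevel=2,
            )
            diff = 0
        undiagnosed[k] = diff
    return estimated, undiagnosed


def cost_undiagnosed(
    undiagnosed: dict[str, int],
    per_person_cost: dict[str, float],
    diagnosed_total: float,
) -> tuple[dict[str, float], float]:
    """Added cost of undiagnosed cases (same attributable per-person cost as
    diagnosed cases of the stage) and the revised overall total."""
    added = {
        k: undiagnosed[k] * per_person_cost[k] for k in undiagnosed
    }
    revised = diagnosed_total + sum(added.values())
    return added, revised


def extrapolate_national(
    local: pd.DataFrame, national_pop: pd.DataFrame
) -> pd.DataFrame:
    """Transfer stratum-specific case rates to the national population.

    Parameters
    ----------
    local : columns ``STRATUM_KEY + [cases, population, cost_ppy]`` —
        per-stratum case count, local population denominator and
        attributable cost per person-year.
    national_pop : columns ``STRATUM_KEY + [population]`` (stage-invariant
        demographic counts may be repeated across stages).

    Returns per-stratum national case counts and costs.  Strata with local
    cases but zero local population are a data error; strata present
    nationally but absent locally get zero cases (and the stage-marginal
    cost, for reporting) with a warning.
    """
    merged = national_pop.rename(columns={"population": "population_national"}).merge(
        local, on=STRATUM_KEY, how="left"
    )
    merged["cases"] = merged["cases"].fillna(0.0)
    bad = merged[(merged["cases"] > 0) & (merged["population"] <= 0)]
    if len(bad):
        raise ValueError(
            f"strata with cases but zero local population: {len(bad)} rows"
        )
    missing_local = merged["cost_ppy"].isna() & (merged["population_national"] > 0)
    if missing_local.any():
        stage_cost = (
            local.groupby("stage")
            .apply(
                lambda g: (g["cost_ppy"] * g["cases"]).sum() / g["cases"].sum()
                if g["cases"].sum() > 0
                else 0.0,
                include_groups=False,
            )
            .to_dict()
        )
        warnings.warn(
            f"{int(missing_local.sum())} national strata absent locally; "
            "borrowing the stage-marginal per-person cost",
            stacklevel=2,
        )
        merged.loc[missing_local, "cost_ppy"] = merged.loc[
            missing_local, "stage"
        ].map(stage_cost).fillna(0.0)

    rate = merged["cases"].where(merged["population"] > 0, 0.0) / merged[
        "population"
    ].where(merged["population"] > 0, 1.0)
    merged["national_cases"] = rate * merged["population_national"]
    merged["national_cost"] = merged["national_cases"] * merged["cost_ppy"].fillna(0.0)
    return merged[STRATUM_KEY + ["national_cases", "national_cost"]]


def national_summary(extrapolated: pd.DataFrame) -> pd.DataFrame:
    """National case counts and costs by stage, with a grand-total row."""
    by_stage = (
        extrapolated.groupby("stage")[["national_cases", "national_cost"]]
        .sum()
        .reset_index()
    )
    total = pd.DataFrame(
        {
            "stage": ["total"],
            "national_cases": [by_stage["national_cases"].sum()],
            "national_cost": [by_stage["national_cost"].sum()],
        }
    )
    return pd.concat([by_stage, total], ignore_index=True)
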