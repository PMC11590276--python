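"""Attributable-cost aggregation: case-minus-control differences by stage.

The cost attributable to CKD for a case is the per-component difference
between the case's ledger and the matched control's apportioned ledger
over the same window length.  Negative component differences are retained
(truncating at zero would bias totals upward).  Aggregation is per stage
and per person-year: component mean per person-year = Σ differences /
Σ person-years, with a stage total as the sum of its component means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .types import COMPONENTS, CostLedger, STAGES


@dataclass(frozen=True)
class AttributableRecord:
    """Per-case, per-stage-period attributable component costs."""

    case_id: str
    stage: str
    period: tuple[date, date]
    person_years: float
    component_diffs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.component_diffs) != set(COMPONENTS):
            raise ValueError("component_diffs must cover all seven components")
        if not self.person_years > 0:
            raise ValueError("person_years must be positive")


@dataclass
class StageCostTable:
    """Stage × component per-person-year table plus overall totals/shares."""

    person_years: dict[str, float]
    per_person_year: pd.DataFrame  # index: stage; columns: components + "total"
    component_totals: dict[str, float]
    grand_total: float
    shares_pct: dict[str, int]


def attributable_difference(
    case_ledger: CostLedger, control_ledger_apportioned: CostLedger
) -> dict[str, float]:
    """Per-component case − control difference; negatives retained."""
    a, b = case_ledger.components, control_ledger_apportioned.components
    if set(a) != set(b):
        raise ValueError("ledgers carry different component sets")
    return {c: round(a[c] - b[c], 2) for c in COMPONENTS}


def aggregate_by_stage(records: Sequence[AttributableRecord]) -> StageCostTable:
    """Aggregate attributable records into the headline stage table."""
    stages = [s for s in STAGES if any(r.stage == s for r in records)]
    py = {s: sum(r.person_years for r in records if r.stage == s) for s in stages}
    rows = {}
    for s in stages:
        recs = [r for r in records if r.stage == s]
        means = {
            c: sum(r.component_diffs[c] for r in recs) / py[s] for c in COMPONENTS
        }
        means["total"] = sum(means[c] for c in COMPONENTS)
        rows[s] = means
    per_py = pd.DataFrame.from_dict(rows, orient="index").reindex(stages)
    per_py.index.name = "stage"

    component_totals = {
        c: sum(r.component_diffs[c] for r in records) for c in COMPONENTS
    }
    grand_total = sum(component_totals.values())
    shares = (
        compute_shares(component_totals)
        if records and grand_total != 0 and all(v >= 0 for v in component_totals.values())
        else {}
    )
    return StageCostTable(py, per_py, component_totals, grand_total, shares)


def compute_shares(component_totals: Mapping[str, float]) -> dict[str, int]:
    """Percentage share of each component in the grand total, rounded to
    whole percent (half away from zero)."""
    if any(v < 0 for v in component_totals.values()):
        raise ValueError("shares are defined for non-negative totals")
    grand = sum(component_totals.values())
    if grand == 0:
        raise ValueError("all-zero totals: shares undefined")
    return {
        c: int(
            (Decimal(str(v)) / Decimal(str(grand)) * 100).quantize(
                Decimal("1"), rounding=ROUND_HALF_UP
            )
        )
        for c, v in component_totals.items()
    }


def cost_ratio_vs_controls(case_total: float, control_total: float) -> float:
    """Percentage increase of case costs over matched-control costs."""
    if control_total <= 0:
        raise ValueError("control total must be positive")
    return (case_total - control_total) / control_total * 100.0


def round_millions(aud: float) -> int:
    """Round AUD to the nearest million, half away from zero (report scale)."""
    return int(
        (Decimal(str(aud)) / Decimal(1_000_000)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )
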