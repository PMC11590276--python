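"""Pricing rules turning utilisation events into component cost ledgers.

All amounts are computed in integer cents and surfaced as 2023 AUD.  Unit
costs live in a :class:`CostCatalog`; each pricing rule multiplies by the
inflation index for the catalogue's cost year so that a catalogue quoted
in 2019 dollars and one quoted directly in 2023 dollars go through the
same code path (index 1 for 2023).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence

from ._money import scale_cents, to_aud, to_cents
from .types import COMPONENTS, CostLedger, UtilisationEvent

_WEIGHT_TOL = 1e-9


class MissingPriceError(KeyError):
    """A code had no entry in the cost catalogue."""

    def __init__(self, kind: str, codes: Sequence[str]):
        self.kind = kind
        self.codes = tuple(codes)
        super().__init__(f"no {kind} price for: {', '.join(self.codes)}")


@dataclass
class CostCatalog:
    """Unit-cost lookup tables (AUD of ``cost_year``) plus inflation indices.

    ``inflation_index`` maps a price-base year to the multiplier taking it
    to 2023 AUD; the 2023 entry must be 1.  ``emergency_cost_year`` lets
    emergency average costs be quoted in a different base year (e.g. taken
    directly at 2023 values) than the rest of the catalogue.
    """

    drg_unit_costs: dict[str, float]
    emergency_costs: dict[str, float]
    mbs_item_fees: dict[str, float]
    collection_fee: float
    bulk_billing_fee: float
    medication_tier_prices: dict[str, dict[str, float]]
    medication_tier_weights: dict[str, dict[str, float]]
    dispensing_fee: float
    handling_fee: float
    safety_net_recording_fee: float
    inflation_index: dict[int, float] = field(default_factory=lambda: {2023: 1.0})
    cost_year: int = 2019
    emergency_cost_year: Optional[int] = None
    dialysis_drgs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if abs(self.inflation_index.get(2023, float("nan")) - 1.0) > _WEIGHT_TOL:
            raise ValueError("inflation index for 2023 must be 1")
        for table in (self.drg_unit_costs, self.emergency_costs, self.mbs_item_fees):
            if any(v < 0 for v in table.values()):
                raise ValueError("catalogue prices must be non-negative")
        for med, weights in self.medication_tier_weights.items():
            if abs(sum(weights.values()) - 1.0) > 1e-6:
                raise ValueError(f"tier weights for {med!r} do not sum to 1")

    def _index(self, year: int) -> float:
        try:
            return self.inflation_index[year]
        except KeyError:
            raise ValueError(f"no inflation index for year {year}") from None

    def inflate(self, cents: int, year: Optional[int] = None) -> int:
        """Take a cent amount of ``year`` (default the catalogue cost year)
        to 2023 AUD cents."""
        return scale_cents(cents, self._index(self.cost_year if year is None else year))


# ---------------------------------------------------------------------------
# Per-event pricing


def is_dialysis_admission(admission: UtilisationEvent, catalog: CostCatalog) -> bool:
    """Dialysis flag: any Z49* ICD code, or a DRG in the dialysis DRG set."""
    icds = admission.payload.get("icd_codes", ())
    if any(str(c).upper().startswith("Z49") for c in icds):
        return True
    return admission.payload["drg_code"] in catalog.dialysis_drgs


def cost_admission(
    admission: UtilisationEvent, catalog: CostCatalog
) -> tuple[str, float]:
    """Price one hospital separation by its AR-DRG unit cost.

    Returns ``(component, AUD)`` where the component is ``dialysis`` for
    dialysis-flagged separations and ``hospital_nondialysis`` otherwise —
    dialysis admissions are costed in their own category, not in the
    patient's hospital total.
    """
    drg = admission.payload["drg_code"]
    if drg not in catalog.drg_unit_costs:
        raise MissingPriceError("DRG", [drg])
    cents = catalog.inflate(to_cents(catalog.drg_unit_costs[drg]))
    component = "dialysis" if is_dialysis_admission(admission, catalog) else "hospital_nondialysis"
    return component, to_aud(cents)


def cost_emergency(presentation: UtilisationEvent, catalog: CostCatalog) -> float:
    """Price one emergency presentation by the average cost for its episode
    end status."""
    status = presentation.payload["end_status"]
    if status not in catalog.emergency_costs:
        raise MissingPriceError("emergency end-status", [status])
    year = catalog.emergency_cost_year or catalog.cost_year
    return to_aud(catalog.inflate(to_cents(catalog.emergency_costs[status]), year))


def price_medication(medication_code: str, catalog: CostCatalog) -> float:
    """Average government cost of one script of a medication.

    Weighted average of the medication's prices across concessional /
    safety-net tiers (weights from national dispensing frequencies), plus
    the dispensing, handling and PBS Safety Net recording fees.
    """
    if medication_code not in catalog.medication_tier_prices:
        raise MissingPriceError("medication", [medication_code])
    prices = catalog.medication_tier_prices[medication_code]
    weights = catalog.medication_tier_weights[medication_code]
    if abs(sum(weights.values()) - 1.0) > 1e-6:
        raise ValueError(f"tier weights for {medication_code!r} do not sum to 1")
    avg_cents = round(sum(weights[t] * to_cents(prices[t]) for t in prices))
    fees = (
        to_cents(catalog.dispensing_fee)
        + to_cents(catalog.handling_fee)
        + to_cents(catalog.safety_net_recording_fee)
    )
    return to_aud(catalog.inflate(avg_cents + fees))


def cost_prescriptions(
    scripts: Iterable[UtilisationEvent], catalog: CostCatalog
) -> float:
    """Total medication cost: each script costed for its original dispense
    plus all repeats, ``(1 + n_repeats) × per-script price``."""
    total = 0
    for s in scripts:
        n_repeats = int(s.payload["n_repeats"])
        if n_repeats < 0:
            raise ValueError("n_repeats must be non-negative")
        total += (1 + n_repeats) * to_cents(
            price_medication(s.payload["medication_code"], catalog)
        )
    return to_aud(total)


def cost_pathology_collection(
    item_codes: Sequence[str], catalog: CostCatalog
) -> float:
    """Price one community pathology collection under the coning rule.

    Pays the collection and bulk-billing fees plus only the three most
    expensive MBS items in the collection (all of them if fewer than
    three).  Ties at the cut are broken by item code order; the coned sum
    is invariant to the tie-break.
    """
    if not item_codes:
        raise ValueError("empty pathology collection")
    missing = [c for c in item_codes if c not in catalog.mbs_item_fees]
    if missing:
        raise MissingPriceError("MBS item", sorted(set(missing)))
    ranked = sorted(item_codes, key=lambda c: (-to_cents(catalog.mbs_item_fees[c]), c))
    cents = (
        to_cents(catalog.collection_fee)
        + to_cents(catalog.bulk_billing_fee)
        + sum(to_cents(catalog.mbs_item_fees[c]) for c in ranked[:3])
    )
    return to_aud(catalog.inflate(cents))


def cost_gp(visits: Iterable[UtilisationEvent], catalog: CostCatalog) -> float:
    """Total primary-care cost: sum of schedule fees of all billed MBS items."""
    cents = 0
    missing: list[str] = []
    for v in visits:
        for code in v.payload["item_codes"]:
            if code not in catalog.mbs_item_fees:
                missing.append(code)
            else:
                cents += to_cents(catalog.mbs_item_fees[code])
    if missing:
        raise MissingPriceError("MBS item", sorted(set(missing)))
    return to_aud(catalog.inflate(cents))


# ---------------------------------------------------------------------------
# Top-down allocation


def allocate_topdown(total: float, weights: Mapping[str, float]) -> dict[str, float]:
    """Split a top-down total across stages by weight, conserving the total
    to the cent (largest-remainder reconciliation)."""
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    if abs(sum(weights.values()) - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    total_cents = to_cents(total)
    raw = {s: total_cents * w for s, w in weights.items()}
    shares = {s: math.floor(v) for s, v in raw.items()}
    leftover = total_cents - sum(shares.values())
    by_remainder = sorted(raw, key=lambda s: (-(raw[s] - shares[s]), s))
    for s in by_remainder[:leftover]:
        shares[s] += 1
    return {s: to_aud(c) for s, c in shares.items()}


# ---------------------------------------------------------------------------
# Ledger assembly


def build_ledger(
    person_id: str,
    window: tuple[date, date],
    events: Iterable[UtilisationEvent],
    catalog: CostCatalog,
) -> CostLedger:
    """Component-wise cost ledger for one person over a window.

    Events outside the window (inclusive endpoints) are excluded.  Each
    ``pathology_collection`` event is one collection (one person, one
    date, one provider) and is coned independently.  Missing prices across
    all events are aggregated into a single :class:`MissingPriceError`.
    """
    start, end = window
    cents = {c: 0 for c in COMPONENTS}
    missing: dict[str, set[str]] = {}

    def _try(fn, *args):
        try:
            return fn(*args)
        except MissingPriceError as e:
            missing.setdefault(e.kind, set()).update(e.codes)
            return None

    for ev in events:
        if ev.person_id != person_id or not (start <= ev.date <= end):
            continue
        if ev.kind == "admission":
            priced = _try(cost_admission, ev, catalog)
            if priced is not None:
                component, aud = priced
                cents[component] += to_cents(aud)
        elif ev.kind == "emergency":
            aud = _try(cost_emergency, ev, catalog)
            if aud is not None:
                cents["emergency"] += to_cents(aud)
        elif ev.kind == "prescription":
            aud = _try(cost_prescriptions, [ev], catalog)
            if aud is not None:
                cents["medication"] += to_cents(aud)
        elif ev.kind == "gp_visit":
            aud = _try(cost_gp, [ev], catalog)
            if aud is not None:
                cents["primary_care"] += to_cents(aud)
        elif ev.kind == "pathology_collection":
            aud = _try(cost_pathology_collection, ev.payload["item_codes"], catalog)
            if aud is not None:
                cents["pathology"] += to_cents(aud)

    if missing:
        kinds = sorted(missing)
        all_codes = [f"{k}:{c}" for k in kinds for c in sorted(missing[k])]
        raise MissingPriceError(" / ".join(kinds), all_codes)
    return CostLedger(person_id, window, {c: to_aud(v) for c, v in cents.items()})
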