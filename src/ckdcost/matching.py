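"""1:1 exact matching of CKD cases to non-CKD controls, with relaxation.

Cases are matched on 5-year age band, sex, indigenous status, remoteness
and evidence of diabetes.  Where no exact match exists the constraints are
relaxed in a fixed order — remoteness, then sex, then indigenous status —
while age band and diabetes are never relaxed.  Matching is greedy over
cases in stable (person_id) order, without replacement, with the control
drawn uniformly at random among those available at the least-relaxed
feasible level.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np

from .types import CostLedger, MatchKey, MatchedPair

#: fields retained at each relaxation level, in relaxation order
_LEVEL_FIELDS = {
    "none": ("age_band", "sex", "indigenous", "remoteness", "diabetes"),
    "remoteness": ("age_band", "sex", "indigenous", "diabetes"),
    "remoteness+sex": ("age_band", "indigenous", "diabetes"),
    "remoteness+sex+indigenous": ("age_band", "diabetes"),
}
LADDER = tuple(_LEVEL_FIELDS)


def _subkey(key: MatchKey, level: str) -> tuple:
    return tuple(getattr(key, f) for f in _LEVEL_FIELDS[level])


def match_cases(
    cases: dict[str, MatchKey],
    control_pool: dict[str, MatchKey],
    seed: int,
    followup_days: dict[str, int] | None = None,
) -> list[MatchedPair]:
    """Match each case to an unused control at the least-relaxed feasible level.

    Parameters
    ----------
    cases, control_pool : person_id → MatchKey; the two must be disjoint.
    seed : seeds the uniform draw among eligible controls within a level.
    followup_days : case person_id → follow-up days (defaults to 365).

    Returns one :class:`MatchedPair` per case, in sorted case-id order;
    cases with no eligible control at any level are ``unmatched``.
    """
    overlap = set(cases) & set(control_pool)
    if overlap:
        raise ValueError(f"control pool overlaps cases: {sorted(overlap)[:5]}")
    if not control_pool:
        warnings.warn("empty control pool: all cases unmatched", stacklevel=2)

    rng = np.random.default_rng(seed)
    followup_days = followup_days or {}

    # level → subkey → sorted list of available control ids
    index: dict[str, dict[tuple, list[str]]] = {lvl: {} for lvl in LADDER}
    for cid in sorted(control_pool):
        key = control_pool[cid]
        for lvl in LADDER:
            index[lvl].setdefault(_subkey(key, lvl), []).append(cid)
    used: set[str] = set()

    pairs: list[MatchedPair] = []
    for case_id in sorted(cases):
        key = cases[case_id]
        days = int(followup_days.get(case_id, 365))
        chosen, level = None, "unmatched"
        for lvl in LADDER:
            bucket = index[lvl].get(_subkey(key, lvl), [])
            avail = [c for c in bucket if c not in used]
            if avail:
                chosen = avail[int(rng.integers(len(avail)))]
                level = lvl
                used.add(chosen)
                break
        pairs.append(MatchedPair(case_id, chosen, level, days))
    return pairs


def match_summary(pairs: list[MatchedPair]) -> dict[str, int]:
    """Counts of pairs per relaxation level (match-quality report)."""
    counts = Counter(p.relaxation_level for p in pairs)
    return {lvl: counts.get(lvl, 0) for lvl in LADDER + ("unmatched",)}


def apportion_control(pair: MatchedPair, control_annual_costs: CostLedger) -> CostLedger:
    """Scale a control's annual ledger to the case's follow-up length.

    Each matched control is apportioned the same follow-up as its case:
    every component is multiplied by ``case_followup_days / 365``.
    """
    if not 1 <= pair.case_followup_days <= 365:
        raise ValueError("case follow-up days must be in [1, 365]")
    return control_annual_costs.scaled(pair.case_followup_days / 365.0)
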