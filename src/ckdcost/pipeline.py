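"""End-to-end pipeline: simulate → stage → match → cost → model → attribute.

This is the driver the analysis scripts and the acceptance checks run.
Component conventions:

* emergency, non-dialysis hospital and (admission-based) dialysis costs are
  priced per event within each stage period;
* medication, primary-care and pathology costs are annual per-person
  amounts — observed in the primary-care extract / provider-complete
  subset, transferred to everyone by gamma/log-link GLM when
  ``use_cost_models`` is on — scaled to each period's length;
* renal outpatient services and home-based dialysis are top-down
  allocations spread over stage person-years (controls contribute zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .attribution import (
    AttributableRecord,
    StageCostTable,
    aggregate_by_stage,
    attributable_difference,
    cost_ratio_vs_controls,
)
from .cost_model import (
    CostModelFit,
    CostModelSpec,
    fit_cost_glm,
    predict_costs,
    select_complete_provider_subset,
)
from .costing import CostCatalog, allocate_topdown, build_ledger, is_dialysis_admission
from .matching import MatchedPair, match_cases, match_summary
from .staging import (
    UnstageableError,
    build_stage_history,
    derive_diabetes_flag,
    resolve_followup,
)
from .synthetic import (
    MAIN_PATHOLOGY_PROVIDER,
    SimConfig,
    generate_cohort,
    generate_cost_catalog,
    generate_population_strata,
)
from .types import (
    CostLedger,
    FollowUpWindow,
    MatchKey,
    PersonRecord,
    STAGES,
    StagePeriod,
)

MODELLED_COMPONENTS = ("medication", "primary_care", "pathology")
EVENT_COMPONENTS = ("emergency", "hospital_nondialysis", "dialysis")


@dataclass
class PipelineResult:
    config: SimConfig
    catalog: CostCatalog
    persons: dict[str, PersonRecord]
    truth: pd.DataFrame
    followups: dict[str, FollowUpWindow]
    exclusions: pd.DataFrame
    histories: dict[str, list[StagePeriod]]
    case_ids: list[str]
    control_pool_ids: list[str]
    pairs: list[MatchedPair]
    pair_summary: dict[str, int]
    records: list[AttributableRecord]
    stage_table: StageCostTable
    pct_increase_vs_controls: float
    fits: dict[str, CostModelFit]
    local_strata: pd.DataFrame
    national_strata: pd.DataFrame
    stratum_cases: pd.DataFrame


def _modal_stage(history: list[StagePeriod], window: FollowUpWindow) -> str:
    """Stage occupying the most follow-up days; 'none' if no history."""
    if not history:
        return "none"
    days: dict[str, int] = {}
    for p in history:
        days[p.stage] = days.get(p.stage, 0) + p.days
    return max(days, key=lambda s: (days[s], s))


def run_pipeline(
    config: SimConfig, use_cost_models: bool = True
) -> PipelineResult:
    persons, labs, events, truth = generate_cohort(config)
    catalog = generate_cost_catalog(config)
    year = config.analysis_year
    year_window = (date(year, 1, 1), date(year, 12, 31))

    labs_by_person: dict[str, list] = {}
    for l in labs:
        labs_by_person.setdefault(l.person_id, []).append(l)
    events_by_person: dict[str, list] = {}
    for e in events:
        events_by_person.setdefault(e.person_id, []).append(e)

    # --- follow-up resolution and staging -------------------------------
    followups: dict[str, FollowUpWindow] = {}
    histories: dict[str, list[StagePeriod]] = {}
    exclusion_rows: list[dict] = []
    diabetes: dict[str, bool] = {}
    for p in persons:
        plabs = labs_by_person.get(p.person_id, [])
        pevents = events_by_person.get(p.person_id, [])
        record_dates = [l.date for l in plabs] + [
            e.date
            for e in pevents
            if e.kind in ("admission", "emergency", "pathology_collection")
        ]
        fu = resolve_followup(p, record_dates, year)
        followups[p.person_id] = fu
        if fu.excluded:
            exclusion_rows.append(
                {"person_id": p.person_id, "reason": fu.exclusion_reason}
            )
            histories[p.person_id] = []
            continue
        diabetes[p.person_id] = derive_diabetes_flag(plabs)
        dialysis_dates = [
            e.date
            for e in pevents
            if e.kind == "admission" and is_dialysis_admission(e, catalog)
        ]
        try:
            histories[p.person_id] = build_stage_history(
                plabs, dialysis_dates, fu, p.sex, p.age_midpoint
            )
        except UnstageableError:
            histories[p.person_id] = []
            followups[p.person_id] = FollowUpWindow(
                p.person_id, fu.start_date, fu.end_date,
                excluded=True, exclusion_reason="unstageable",
            )
            exclusion_rows.append(
                {"person_id": p.person_id, "reason": "unstageable"}
            )
    exclusions = pd.DataFrame(exclusion_rows, columns=["person_id", "reason"])

    included = [p for p in persons if not followups[p.person_id].excluded]
    case_ids = [p.person_id for p in included if histories[p.person_id]]
    control_pool_ids = [p.person_id for p in included if not histories[p.person_id]]
    by_id = {p.person_id: p for p in persons}

    # --- matching --------------------------------------------------------
    def key(pid: str) -> MatchKey:
        p = by_id[pid]
        return MatchKey(p.age_band, p.sex, p.indigenous, p.remoteness,
                        diabetes.get(pid, False))

    pairs = match_cases(
        {c: key(c) for c in case_ids},
        {c: key(c) for c in control_pool_ids},
        seed=config.seed + 1,
        followup_days={c: followups[c].days for c in case_ids},
    )

    # --- annual event-based ledgers --------------------------------------
    annual: dict[str, CostLedger] = {}
    for p in included:
        annual[p.person_id] = build_ledger(
            p.person_id, year_window, events_by_person.get(p.person_id, []), catalog
        )

    # --- GLM transfer of medication / GP / pathology costs ---------------
    rows = pd.DataFrame(
        {
            "person_id": [p.person_id for p in included],
            "stage": [
                _modal_stage(histories[p.person_id], followups[p.person_id])
                for p in included
            ],
            "sex": [p.sex for p in included],
            "age_band": [p.age_band for p in included],
            "indigenous": [p.indigenous for p in included],
            "remoteness": [p.remoteness for p in included],
        }
    )
    for comp in MODELLED_COMPONENTS:
        rows[comp] = [annual[pid].components[comp] for pid in rows["person_id"]]

    fits: dict[str, CostModelFit] = {}
    modelled: dict[str, pd.Series] = {}
    if use_cost_models:
        in_extract = set(truth.loc[truth["in_gp_extract"], "person_id"])
        path_tests = [
            (e.person_id, e.payload["provider_id"])
            for e in events
            if e.kind == "pathology_collection"
        ]
        provider_complete = select_complete_provider_subset(
            path_tests, MAIN_PATHOLOGY_PROVIDER, threshold=0.95
        )
        training_ids = {
            "medication": in_extract,
            "primary_care": in_extract,
            "pathology": provider_complete,
        }
        for comp in MODELLED_COMPONENTS:
            train = rows[rows["person_id"].isin(training_ids[comp])]
            spec = CostModelSpec(response=comp)
            fit = fit_cost_glm(spec, train)
            fits[comp] = fit
            # rows whose levels were all seen in training get predictions;
            # the rest keep their observed costs
            seen = np.ones(len(rows), dtype=bool)
            for pred, lvls in fit.levels.items():
                seen &= rows[pred].isin(lvls).to_numpy()
            if not seen.all():
                warnings.warn(
                    f"{comp}: {(~seen).sum()} persons with predictor levels "
                    "unseen in training keep observed costs",
                    stacklevel=2,
                )
            predicted = pd.Series(rows[comp].to_numpy(), index=rows.index, dtype=float)
            predicted.loc[seen] = np.round(
                predict_costs(fit, rows.loc[seen]), 2
            )
            modelled[comp] = predicted
    else:
        for comp in MODELLED_COMPONENTS:
            modelled[comp] = rows[comp].astype(float)

    modelled_by_pid = {
        comp: dict(zip(rows["person_id"], modelled[comp])) for comp in MODELLED_COMPONENTS
    }

    # --- top-down totals --------------------------------------------------
    stage_py = {s: 0.0 for s in STAGES}
    for cid in case_ids:
        for period in histories[cid]:
            stage_py[period.stage] += period.person_years
    outpatient_rate = {
        s: config.outpatient_ppy_by_stage.get(s, 0.0) for s in STAGES
    }
    outpatient_total = sum(outpatient_rate[s] * stage_py[s] for s in STAGES)
    if outpatient_total > 0:
        weights = {
            s: outpatient_rate[s] * stage_py[s] / outpatient_total for s in STAGES
        }
        outpatient_alloc = allocate_topdown(round(outpatient_total, 2), weights)
    else:
        outpatient_alloc = {s: 0.0 for s in STAGES}
    home_dialysis_total = config.home_dialysis_ppy * stage_py.get("5", 0.0)
    home_dialysis_alloc = (
        allocate_topdown(round(home_dialysis_total, 2), {"5": 1.0})
        if home_dialysis_total > 0
        else {"5": 0.0}
    )

    # --- per-period ledgers and attribution ------------------------------
    records: list[AttributableRecord] = []
    case_totals = 0.0
    control_totals = 0.0
    for pair in pairs:
        if pair.control_id is None:
            continue
        cid = pair.case_id
        control_annual = annual[pair.control_id]
        for period in histories[cid]:
            frac = period.person_years
            case_ledger = build_ledger(
                cid, (period.start_date, period.end_date),
                events_by_person.get(cid, []), catalog,
            )
            comps = dict(case_ledger.components)
            for comp in MODELLED_COMPONENTS:
                comps[comp] = round(modelled_by_pid[comp][cid] * frac, 2)
            if stage_py[period.stage] > 0:
                comps["outpatient"] = round(
                    outpatient_alloc.get(period.stage, 0.0)
                    * frac / stage_py[period.stage], 2,
                )
                if period.stage == "5":
                    comps["dialysis"] = round(
                        comps["dialysis"]
                        + home_dialysis_alloc["5"] * frac / stage_py["5"], 2,
                    )
            case_period = CostLedger(cid, (period.start_date, period.end_date), comps)

            ctl_comps = {
                c: v for c, v in control_annual.components.items()
            }
            for comp in MODELLED_COMPONENTS:
                ctl_comps[comp] = modelled_by_pid[comp][pair.control_id]
            ctl_annual = CostLedger(pair.control_id, year_window, ctl_comps)
            ctl_period = ctl_annual.scaled(period.days / 365.0)

            diffs = attributable_difference(case_period, ctl_period)
            records.append(
                AttributableRecord(
                    cid, period.stage,
                    (period.start_date, period.end_date),
                    period.person_years, diffs,
                )
            )
            case_totals += case_period.total
            control_totals += ctl_period.total

    stage_table = aggregate_by_stage(records)
    pct_increase = (
        cost_ratio_vs_controls(case_totals, control_totals)
        if control_totals > 0
        else float("nan")
    )

    # --- strata for extrapolation ----------------------------------------
    strat_rows = []
    for cid in case_ids:
        p = by_id[cid]
        for s in {per.stage for per in histories[cid]}:
            strat_rows.append(
                {"stage": s, "sex": p.sex, "indigenous": p.indigenous,
                 "age_band": p.age_band, "remoteness": p.remoteness}
            )
    stratum_cases = (
        pd.DataFrame(strat_rows)
        .groupby(["stage", "sex", "indigenous", "age_band", "remoteness"])
        .size()
        .reset_index(name="cases")
        if strat_rows
        else pd.DataFrame(
            columns=["stage", "sex", "indigenous", "age_band", "remoteness", "cases"]
        )
    )
    local_strata, national_strata = generate_population_strata(config, stratum_cases)

    return PipelineResult(
        config=config,
        catalog=catalog,
        persons=by_id,
        truth=truth,
        followups=followups,
        exclusions=exclusions,
        histories=histories,
        case_ids=case_ids,
        control_pool_ids=control_pool_ids,
        pairs=pairs,
        pair_summary=match_summary(pairs),
        records=records,
        stage_table=stage_table,
        pct_increase_vs_controls=pct_increase,
        fits=fits,
        local_strata=local_strata,
        national_strata=national_strata,
        stratum_cases=stratum_cases,
    )


def per_person_stage_cost(result: PipelineResult) -> dict[str, float]:
    """Average attributable cost per case, by stage (extrapolation input)."""
    totals: dict[str, float] = {}
    counts: dict[str, set] = {}
    for r in result.records:
        totals[r.stage] = totals.get(r.stage, 0.0) + sum(r.component_diffs.values())
        counts.setdefault(r.stage, set()).add(r.case_id)
    return {s: totals[s] / len(counts[s]) for s in totals}


def local_stratum_table(result: PipelineResult) -> pd.DataFrame:
    """Stratum table (cases, local population, per-person cost) for transfer."""
    cost = per_person_stage_cost(result)
    table = result.stratum_cases.merge(
        result.local_strata,
        on=["stage", "sex", "indigenous", "age_band", "remoteness"],
        how="left",
    )
    table["cost_ppy"] = table["stage"].map(cost).fillna(0.0)
    return table


def attributable_mean_and_se(
    result: PipelineResult, stage: str, component: str
) -> tuple[float, float, int]:
    """Ratio-estimator mean per person-year and its standard error.

    mean = Σ diffs / Σ person-years over the stage's records; the SE is
    the linearised (delta-method) SE of that ratio.
    """
    recs = [r for r in result.records if r.stage == stage]
    if not recs:
        return float("nan"), float("nan"), 0
    x = np.array([r.component_diffs[component] for r in recs])
    t = np.array([r.person_years for r in recs])
    ratio = x.sum() / t.sum()
    resid = x - ratio * t
    se = float(np.sqrt((resid**2).sum()) / t.sum())
    return float(ratio), se, len(recs)
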