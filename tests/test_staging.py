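"""Staging: eGFR computation, chronicity detection, KDIGO stage history."""

from datetime import date, timedelta

import numpy as np
import pytest

from ckdcost.staging import (
    UnstageableError,
    assign_kdigo_stage,
    build_stage_history,
    compute_egfr,
    derive_diabetes_flag,
    detect_ckd,
    resolve_followup,
)
from ckdcost.synthetic import invert_egfr
from ckdcost.types import FollowUpWindow, LabResult, PersonRecord, STAGE_SEVERITY


def creat(pid, d, egfr_target, age, sex):
    """Creatinine lab whose eGFR equals the target (inverted CKD-EPI)."""
    return LabResult(pid, d, "creatinine", invert_egfr(egfr_target, age, sex))


# ---------------------------------------------------------------------------
# CKD-EPI 2009


class TestComputeEgfr:
    # expected values evaluated independently from the published closed form
    @pytest.mark.parametrize(
        "sex,age,creat_umol,expected",
        [
            ("female", 50, 61.9, 101.0),  # 0.70 mg/dL, below kappa
            ("male", 70, 159.0, 37.3),    # 1.80 mg/dL, above kappa
        ],
    )
    def test_reference_values(self, sex, age, creat_umol, expected):
        assert compute_egfr(creat_umol, age, sex) == pytest.approx(expected, abs=1.0)

    def test_monotone_decreasing_in_creatinine(self):
        grid = np.linspace(30, 900, 60)
        values = [compute_egfr(c, 60, "male") for c in grid]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_doubling_creatinine_lowers_egfr(self):
        assert compute_egfr(140, 55, "female") > compute_egfr(280, 55, "female")

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(ValueError):
            compute_egfr(0.0, 50, "male")

    def test_inversion_roundtrip(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            target = float(rng.uniform(5, 120))
            age = float(rng.uniform(20, 95))
            sex = "male" if rng.random() < 0.5 else "female"
            assert compute_egfr(invert_egfr(target, age, sex), age, sex) == pytest.approx(
                target, rel=1e-9
            )


# ---------------------------------------------------------------------------
# Chronicity detection


class TestDetectCkd:
    def test_pair_over_90_days_confirms(self):
        labs = [
            creat("p", date(2019, 1, 1), 55, 70, "male"),
            creat("p", date(2019, 4, 11), 55, 70, "male"),  # day 100
        ]
        assert detect_ckd(labs, "male", 70) == date(2019, 4, 11)

    def test_interim_above_60_breaks_window(self):
        labs = [
            creat("p", date(2019, 1, 1), 55, 70, "male"),
            creat("p", date(2019, 2, 20), 65, 70, "male"),  # day 50
            creat("p", date(2019, 4, 11), 55, 70, "male"),
        ]
        assert detect_ckd(labs, "male", 70) is None

    def test_window_of_exactly_90_days_or_less_insufficient(self):
        labs = [
            creat("p", date(2019, 1, 1), 55, 70, "male"),
            creat("p", date(2019, 3, 2), 55, 70, "male"),  # day 60
        ]
        assert detect_ckd(labs, "male", 70) is None
        labs90 = [
            creat("p", date(2019, 1, 1), 55, 70, "male"),
            creat("p", date(2019, 4, 1), 55, 70, "male"),  # exactly 90 days apart
        ]
        assert detect_ckd(labs90, "male", 70) is None

    def test_uacr_pathway_with_sex_threshold(self):
        labs = [
            LabResult("p", date(2019, 1, 1), "uacr", 3.0),
            LabResult("p", date(2019, 5, 1), "uacr", 3.0),
        ]
        # 3.0 mg/mmol is albuminuria for males (>= 2.5) but not females (< 3.5)
        assert detect_ckd(labs, "male", 60) == date(2019, 5, 1)
        assert detect_ckd(labs, "female", 60) is None

    def test_unsorted_input_rejected(self):
        labs = [
            creat("p", date(2019, 4, 11), 55, 70, "male"),
            creat("p", date(2019, 1, 1), 55, 70, "male"),
        ]
        with pytest.raises(ValueError, match="sorted"):
            detect_ckd(labs, "male", 70)


# ---------------------------------------------------------------------------
# KDIGO stage assignment


class TestAssignStage:
    @pytest.mark.parametrize(
        "egfr,alb,expected",
        [
            (92, True, "1"),
            (92, False, None),
            (72, True, "2"),
            (72, False, None),
            (50, False, "3a"),
            (50, True, "3a"),
            (40, False, "3b"),
            (20, False, "4"),
            (14, False, "5"),
            (90, True, "1"),
            (60, True, "2"),
            (45, False, "3a"),
            (30, False, "3b"),
            (15, False, "4"),
        ],
    )
    def test_bands(self, egfr, alb, expected):
        assert assign_kdigo_stage(egfr, alb) == expected


# ---------------------------------------------------------------------------
# Stage history


def full_year_window(pid="p", year=2019):
    return FollowUpWindow(pid, date(year, 1, 1), date(year, 12, 31))


class TestBuildStageHistory:
    def test_pair_spanning_two_stages_opens_at_least_severe(self):
        labs = [
            creat("p", date(2019, 1, 1), 50, 70, "male"),   # 3a
            creat("p", date(2019, 5, 1), 40, 70, "male"),   # 3b
        ]
        periods = build_stage_history(labs, [], full_year_window(), "male", 70)
        assert periods[0].stage == "3a"
        assert periods[0].start_date == date(2019, 5, 1)

    def test_ratchet_ignores_later_improvement(self):
        labs = [
            creat("p", date(2018, 1, 1), 40, 70, "male"),
            creat("p", date(2018, 6, 1), 40, 70, "male"),
            creat("p", date(2019, 3, 1), 65, 70, "male"),
            creat("p", date(2019, 9, 1), 70, 70, "male"),
        ]
        periods = build_stage_history(labs, [], full_year_window(), "male", 70)
        assert [p.stage for p in periods] == ["3b"]
        assert periods[0].start_date == date(2019, 1, 1)
        assert periods[0].end_date == date(2019, 12, 31)

    def test_dialysis_event_splits_period_on_its_date(self):
        labs = [
            creat("p", date(2018, 3, 1), 50, 70, "male"),
            creat("p", date(2018, 8, 1), 50, 70, "male"),
        ]
        periods = build_stage_history(
            labs, [date(2019, 7, 1)], full_year_window(), "male", 70
        )
        assert [(p.stage, p.start_date, p.end_date) for p in periods] == [
            ("3a", date(2019, 1, 1), date(2019, 6, 30)),
            ("5", date(2019, 7, 1), date(2019, 12, 31)),
        ]

    def test_no_confirmed_ckd_gives_empty_history(self):
        labs = [creat("p", date(2019, 1, 1), 80, 70, "male")]
        assert build_stage_history(labs, [], full_year_window(), "male", 70) == []

    def test_uacr_confirmation_without_egfr_is_unstageable(self):
        labs = [
            LabResult("p", date(2019, 1, 1), "uacr", 9.0),
            LabResult("p", date(2019, 6, 1), "uacr", 9.0),
        ]
        with pytest.raises(UnstageableError):
            build_stage_history(labs, [], full_year_window(), "female", 50)

    def test_uacr_with_high_egfr_gives_stage_1(self):
        labs = [
            creat("p", date(2019, 1, 1), 100, 50, "female"),
            LabResult("p", date(2019, 1, 1), "uacr", 9.0),
            LabResult("p", date(2019, 6, 1), "uacr", 9.0),
        ]
        periods = build_stage_history(labs, [], full_year_window(), "female", 50)
        assert [p.stage for p in periods] == ["1"]

    def test_permutation_safety(self):
        rng = np.random.default_rng(3)
        labs = [
            creat("p", date(2018, 1, 1) + timedelta(days=int(d)), float(e), 70, "male")
            for d, e in zip(rng.integers(0, 700, 12), rng.uniform(20, 90, 12))
        ] + [
            LabResult("p", date(2018, 1, 1) + timedelta(days=int(d)), "uacr", float(u))
            for d, u in zip(rng.integers(0, 700, 6), rng.uniform(0.5, 20, 6))
        ]
        base = build_stage_history(labs, [], full_year_window(), "male", 70)
        for _ in range(5):
            rng.shuffle(labs)
            assert build_stage_history(labs, [], full_year_window(), "male", 70) == base


# ---------------------------------------------------------------------------
# Brute-force day-by-day oracle


def oracle_stage_history(labs, dialysis_dates, followup, sex, age):
    """Recompute the most-severe-confirmed stage for every calendar day by
    direct enumeration of all qualifying pairs (independent of the interval
    construction)."""
    from ckdcost.staging import albuminuria_positive, compute_egfr

    egfr = sorted(
        [(l.date, compute_egfr(l.value, age, sex)) for l in labs if l.analyte == "creatinine"]
    )
    uacr = sorted([(l.date, l.value) for l in labs if l.analyte == "uacr"])

    confirmations = []  # (date, severity)
    for i in range(len(egfr)):
        for j in range(i + 1, len(egfr)):
            di, vi = egfr[i]
            dj, vj = egfr[j]
            if (dj - di).days <= 90:
                continue
            inside = [v for d, v in egfr if di <= d <= dj]
            if all(v < 60 for v in inside):
                si = STAGE_SEVERITY[assign_kdigo_stage(vi, False)]
                sj = STAGE_SEVERITY[assign_kdigo_stage(vj, False)]
                confirmations.append((dj, min(si, sj)))
    for i in range(len(uacr)):
        for j in range(i + 1, len(uacr)):
            di, vi = uacr[i]
            dj, vj = uacr[j]
            if (dj - di).days <= 90:
                continue
            inside = [v for d, v in uacr if di <= d <= dj]
            if all(albuminuria_positive(v, sex) for v in inside):
                prior = [v for d, v in egfr if d <= dj]
                if not prior:
                    raise UnstageableError("no eGFR before uACR confirmation")
                stage = assign_kdigo_stage(prior[-1], True)
                confirmations.append((dj, STAGE_SEVERITY[stage]))
    for d in dialysis_dates:
        confirmations.append((d, STAGE_SEVERITY["5"]))

    inv = {v: k for k, v in STAGE_SEVERITY.items()}
    day_stage = []
    d = followup.start_date
    while d <= followup.end_date:
        sev = max([s for cd, s in confirmations if cd <= d], default=0)
        day_stage.append((d, inv[sev]))
        d += timedelta(days=1)

    periods = []
    for d, s in day_stage:
        if s == "none":
            continue
        if periods and periods[-1][0] == s and periods[-1][2] == d - timedelta(days=1):
            periods[-1][2] = d
        else:
            periods.append([s, d, d])
    return [(s, a, b) for s, a, b in periods]


class TestOracleEquivalence:
    def test_interval_construction_matches_day_by_day_oracle(self):
        """On random ≤200-person cohorts the interval construction agrees
        exactly with brute-force daily evaluation."""
        rng = np.random.default_rng(7)
        followup = full_year_window()
        mismatches = 0
        for i in range(200):
            sex = "male" if rng.random() < 0.5 else "female"
            age = float(rng.uniform(25, 90))
            n_cr = int(rng.integers(0, 8))
            n_ua = int(rng.integers(0, 5))
            labs = [
                creat("p", date(2018, 1, 1) + timedelta(days=int(d)), float(e), age, sex)
                for d, e in zip(rng.integers(0, 730, n_cr), rng.uniform(8, 100, n_cr))
            ] + [
                LabResult("p", date(2018, 1, 1) + timedelta(days=int(d)), "uacr", float(u))
                for d, u in zip(rng.integers(0, 730, n_ua), rng.uniform(0.5, 15, n_ua))
            ]
            labs.sort(key=lambda l: (l.date, l.analyte, l.value))
            dialysis = (
                [date(2019, 1, 1) + timedelta(days=int(rng.integers(0, 365)))]
                if rng.random() < 0.1
                else []
            )
            try:
                expected = oracle_stage_history(labs, dialysis, followup, sex, age)
            except UnstageableError:
                with pytest.raises(UnstageableError):
                    build_stage_history(labs, dialysis, followup, sex, age)
                continue
            got = build_stage_history(labs, dialysis, followup, sex, age)
            got_tuples = [(p.stage, p.start_date, p.end_date) for p in got]
            if got_tuples != expected:
                mismatches += 1
        assert mismatches == 0

    def test_severity_never_decreases(self):
        rng = np.random.default_rng(13)
        followup = full_year_window()
        for _ in range(100):
            n = int(rng.integers(2, 10))
            labs = sorted(
                (
                    creat("p", date(2018, 1, 1) + timedelta(days=int(d)), float(e), 70, "male")
                    for d, e in zip(rng.integers(0, 730, n), rng.uniform(8, 100, n))
                ),
                key=lambda l: l.date,
            )
            periods = build_stage_history(labs, [], followup, "male", 70)
            sev = [STAGE_SEVERITY[p.stage] for p in periods]
            assert sev == sorted(sev)
            for a, b in zip(periods, periods[1:]):
                assert b.start_date == a.end_date + timedelta(days=1)


# ---------------------------------------------------------------------------
# Follow-up and diabetes


def person(pid="p", death=None):
    return PersonRecord(pid, "male", "70-74", False, "major_cities", False, death)


class TestResolveFollowup:
    def test_no_records_in_or_after_year_excludes(self):
        fu = resolve_followup(person(), [date(2017, 5, 1)], 2019)
        assert fu.excluded and fu.exclusion_reason == "lost_to_follow_up"

    def test_death_in_year_truncates_window(self):
        fu = resolve_followup(person(death=date(2019, 3, 15)), [], 2019)
        assert not fu.excluded
        assert fu.end_date == date(2019, 3, 15)

    def test_later_record_keeps_person_with_full_year_window(self):
        fu = resolve_followup(person(), [date(2021, 2, 1)], 2019)
        assert not fu.excluded
        assert (fu.start_date, fu.end_date) == (date(2019, 1, 1), date(2019, 12, 31))


class TestDiabetesFlag:
    def test_two_high_hba1c_on_distinct_dates(self):
        labs = [
            LabResult("p", date(2019, 1, 1), "hba1c", 6.8),
            LabResult("p", date(2019, 6, 1), "hba1c", 7.0),
        ]
        assert derive_diabetes_flag(labs) is True

    def test_single_high_hba1c_insufficient(self):
        assert derive_diabetes_flag([LabResult("p", date(2019, 1, 1), "hba1c", 7.2)]) is False

    def test_two_high_fasting_glucose(self):
        labs = [
            LabResult("p", date(2019, 1, 1), "fpg", 7.5),
            LabResult("p", date(2019, 2, 1), "fpg", 8.1),
        ]
        assert derive_diabetes_flag(labs) is True

    def test_threshold_is_strict(self):
        labs = [
            LabResult("p", date(2019, 1, 1), "hba1c", 6.5),
            LabResult("p", date(2019, 6, 1), "hba1c", 6.5),
        ]
        assert derive_diabetes_flag(labs) is False
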