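# Methods

This note records the modelling assumptions, numerical conventions and
design choices behind `ckdcost`, and what the synthetic experiments do and
do not demonstrate.

## Staging model

eGFR is the CKD-EPI 2009 creatinine equation without the race coefficient,
matching Australian laboratory reporting practice; creatinine in µmol/L is
converted to mg/dL by dividing by 88.4. Chronicity ("over 90 days apart")
is read strictly: the second test must be more than 90 calendar days after
the first. A confirmation window is invalidated by **any** same-analyte
non-qualifying result dated inside it, including one on the same date as
an endpoint. The confirmation date is the second test of the earliest
qualifying pair, and stage periods begin on it (the boundary day belongs
to the new stage). uACR chronicity uses the same window logic with the
sex-specific cutoffs (≥ 2.5 mg/mmol male, ≥ 3.5 female).

Stage assignment follows KDIGO: Stages 1–2 require albuminuria (eGFR ≥ 60
alone is not CKD); Stages 3a–5 are eGFR bands. A creatinine confirmatory
pair whose endpoints imply different stages contributes the **least
severe** of the two. A uACR confirmation is staged by the most recent eGFR
on or before the confirmation date; if that eGFR is below 60 the pair
contributes the stage of that band (albuminuria plus low eGFR is at least
that severe). A uACR confirmation with no eGFR on or before it cannot be
staged: the person is flagged unstageable and excluded, rather than
defaulted to Stage 1 or 2.

The longitudinal history is a ratchet — the stage at any date is the most
severe stage confirmed at or before it — so later improvement never
lowers the stage. Z49 dialysis codes force Stage 5 from their date. The
interval construction is verified against a brute-force day-by-day
evaluator (recompute the most-severe-confirmed stage for every calendar
day from the raw pair definition) on random cohorts; the two agree
exactly.

Prior-year confirmations carry into the analysis year. Persons with no
pathology, hospital, emergency or mortality record in the analysis year
or later are excluded as lost to follow-up; death truncates follow-up.
Diabetes is re-derived from labs (two separate HbA1c > 6.5% or two
fasting glucose > 7.0 mmol/L on distinct dates).

## Matching

Greedy 1:1 exact matching without replacement, cases processed in sorted
person-id order for reproducibility (no optimal-assignment step: with the
relaxation ladder the greedy solution already leaves no case at a level
while a stricter-level control is unused, which the tests verify
exhaustively on small problems). The relaxation ladder drops remoteness,
then sex, then indigenous status; age band and diabetes are never
relaxed. Within a level the control is drawn uniformly at random under
the run seed. Controls' annual ledgers are scaled by the case's follow-up
fraction (`days/365`), anchored to the analysis year rather than
calendar-aligned to the case's window. Whether the original design
matched with or without replacement is not documented; without
replacement is assumed. A case occupying several stages keeps one
control; attribution is per stage period with both ledgers scaled to the
period length.

## Costing conventions

Money is held in integer cents; rounding (half away from zero) happens at
cent boundaries and report time only. Unit costs live in a catalogue
quoted in a base year with a single per-year inflation multiplier to 2023
AUD (the 2023 entry is pinned to 1); emergency averages may carry their
own base year since published emergency unit costs may only be available
at 2023 values. A pathology "collection" is all items for one person, one
date, one provider; coning pays the three most expensive items plus the
collection and bulk-billing fees, ties broken by item code (the coned sum
is tie-invariant). Top-down allocations (renal outpatient clinics by
stage frequency weights; home dialysis wholly to Stage 5) use
largest-remainder reconciliation so stage shares re-sum to the total to
the cent. Negative attributable components are retained — truncating at
zero would bias totals upward. Person-years use a 365-day year (2019 is
not a leap year). Report-scale millions are rounded half away from zero.

## Cost-transfer models

Gamma GLM with log link, main effects of stage (7 levels, reference
"none"), sex (reference female), 5-year age band (reference youngest
observed), indigenous status (reference non-indigenous) and remoteness
(reference major cities). Fitting is IRLS maximum likelihood via
statsmodels; dispersion is the Pearson statistic over residual degrees of
freedom; the reported log-likelihood is checked in tests against a direct
scipy evaluation of the gamma density. Zero costs are handled by an
epsilon shift (ε = 0.01 AUD) by default — the original analysis does not
document its zero handling — with a positive-only variant (fit on
positives, predictions rescaled by the per-stage positive fraction)
available; the two are not compared by AIC when their estimation rows
differ. Model comparison ranks by AIC with BIC alongside; on
disagreement AIC wins and a warning is emitted. A guard requires at
least 10 rows per estimated term. Pathology models are fit on persons
with strictly more than 95% of pathology tests from the designated
provider.

In the pipeline, predictions replace the observed medication, GP and
pathology components for all persons whose predictor levels were seen in
training; rare unseen levels (possible for sparse stages in a small
extract) fall back to observed costs with a warning rather than failing
the run.

## Synthetic data: what it emulates and what it does not

The generator assigns a true stage first (default mix: 90% no CKD, the
remainder split to mirror the relative stage sizes of an administratively
ascertained cohort — Stage 3a dominant, Stages 1–2 scarce because
diagnosis requires uACR testing, whose coverage is set at 24%). Lab
trajectories are built backward from the stage: a confirmatory pair 91–365
days apart inside the stage's eGFR (or uACR) band, interim results
consistent with the window rule, creatinine obtained by inverting the
CKD-EPI equation at the band target. About 70% of cases confirm in the
prior year (carrying forward), the rest mid-year. A configurable 5% of
CKD trajectories carry an inconsistent interim result and must be
rejected by staging; these persons also receive no dialysis-coded
admissions, which would otherwise identify them regardless of labs.
Diabetes labs are generated consistently with the diabetes flag so the
flag is re-derivable. Ages are bands; the band midpoint feeds eGFR.

Annual component costs are zero-inflated gamma (the point mass reflects
the majority with no admissions; the gamma tail matches expenditure skew
and the downstream model family). The configured mean is the
*unconditional* annual mean in 2023 AUD; defaults equal a plausible
non-CKD baseline plus stage-specific attributable increments, with the
Stage-5 dialysis mean split between admission-based sessions and a
top-down home-dialysis allocation. Event counts are the target cost over
the unit price with stochastic rounding, so expected priced cost equals
the drawn target exactly despite discrete event prices. Death (2%)
truncates follow-up; 2% of persons are lost to follow-up by design.
Population strata are the cohort's case strata scaled by a local
population multiplier, and national strata are a further fixed multiple —
so the national/local cost ratio is known and the rate-transfer identity
and linearity are checkable exactly.

The generator does **not** attempt to mimic real prevalence levels,
record-linkage error, provider-specific test menus, or correlation
between components within a person beyond the shared stage; passing tests
demonstrate the pipeline's internal correctness and statistical
calibration under the stated data-generating process, not agreement with
any real jurisdiction's totals.

## Problem sizes and numerical choices

The test suite runs the end-to-end cohort at n = 10,000 (about 900–1,000
cases), GLM coefficient recovery at n = 20,000 over 10 replicates
(mean error per coefficient < 0.02), Wald coverage over 100 replicates at
n = 5,000 (≥ 90% per coefficient), and oracle equivalence suites at ≤ 200
staging cohorts and ≤ 50-case matching problems; these sizes give stable
statistical checks in well under the suite's runtime budget on one CPU.
The end-to-end recovery check compares each stage's attributable cost
per person-year (ratio estimator, Σ diffs / Σ person-years) with the
configured value within three delta-method standard errors; it is run
with observed rather than modelled medication/GP/pathology components,
since the GLM transfer collapses within-stage variation to its
conditional mean and would invalidate the empirical standard error. The
GLM route has its own calibration checks (parameter recovery, coverage,
stratum-mean agreement).

## Undiagnosed and national extrapolation

Survey proportions (5.7% / 9.7%), the 66% persistence fraction, and the
published estimated counts are *inputs*, not re-derived quantities. The
estimated count is computed in full precision and rounded once before
subtracting the observed count; a negative difference floors at zero with
a warning. National transfer divides stratum case counts by local
population and multiplies by national population; strata present
nationally but absent locally contribute zero cases and borrow the
stage-marginal per-person cost for reporting, with a warning. No
uncertainty is propagated through the survey proportions (none is
available for them).

## Known limitations

* Costs within a person are independent across components given stage;
  real comorbidity induces correlation the generator does not model.
* The matching step is greedy; with pathological pools a non-greedy
  assignment could match more cases exactly, though never more cases
  overall at the strictest level than the exhaustive check certifies.
* Stage 5 does not distinguish dialysis modalities or transplant status.
* The per-script medication price uses national tier weights; individual
  concession histories are not simulated.
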