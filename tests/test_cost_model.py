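"""Gamma/log-link cost models: fitting, selection, prediction, transfer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ckdcost.cost_model import (
    CostModelSpec,
    compare_models,
    comparison_table,
    fit_cost_glm,
    predict_costs,
    select_complete_provider_subset,
)
from ckdcost.types import AGE_BANDS, REMOTENESS, STAGES_WITH_NONE


# ---------------------------------------------------------------------------
# Simulation helpers (independent of the fitter)


def simulate(n, rng, shape, coeffs, predictors=("stage", "sex")):
    """Draw predictors uniformly and costs from a gamma/log-link truth."""
    rows = pd.DataFrame(index=range(n))
    if "stage" in predictors:
        rows["stage"] = rng.choice(STAGES_WITH_NONE, size=n)
    if "sex" in predictors:
        rows["sex"] = rng.choice(["female", "male"], size=n)
    if "age_band" in predictors:
        rows["age_band"] = rng.choice(AGE_BANDS, size=n)
    if "indigenous" in predictors:
        rows["indigenous"] = rng.random(n) < 0.5
    if "remoteness" in predictors:
        rows["remoteness"] = rng.choice(REMOTENESS, size=n)
    eta = np.full(n, coeffs["const"])
    for term, beta in coeffs.items():
        if term == "const":
            continue
        p, lvl = term.split("[")
        lvl = lvl.rstrip("]")
        if p == "indigenous":
            eta += beta * (rows[p].astype(str) == lvl).to_numpy()
        else:
            eta += beta * (rows[p] == lvl).to_numpy()
    mu = np.exp(eta)
    rows["cost"] = rng.gamma(shape, mu / shape)
    return rows


TRUE_SIMPLE = {
    "const": 6.0,
    "stage[1]": 0.40, "stage[2]": 0.30, "stage[3a]": 0.15, "stage[3b]": 0.35,
    "stage[4]": 0.60, "stage[5]": 1.50,
    "sex[male]": 0.10,
}


# ---------------------------------------------------------------------------
# Provider-completeness subset


class TestProviderSubset:
    def test_all_tests_with_provider_included(self):
        tests = [("a", "WDP")] * 20
        assert select_complete_provider_subset(tests, "WDP") == {"a"}

    def test_share_exactly_at_threshold_excluded(self):
        tests = [("a", "WDP")] * 19 + [("a", "OTHER")]  # share 0.95, strict >
        assert select_complete_provider_subset(tests, "WDP") == set()

    def test_person_with_no_tests_excluded(self):
        tests = [("b", "WDP")]
        assert select_complete_provider_subset(tests, "WDP") == {"b"}
        assert "a" not in select_complete_provider_subset(tests, "WDP")

    def test_dataframe_input(self):
        df = pd.DataFrame({"person_id": ["a"] * 3 + ["b"] * 3,
                           "provider_id": ["WDP"] * 3 + ["WDP", "X", "X"]})
        assert select_complete_provider_subset(df, "WDP") == {"a"}


# ---------------------------------------------------------------------------
# Fitting


class TestFitCostGlm:
    def test_intercept_only_fitted_mean_is_sample_mean(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(2.0, 50.0, size=400)
        rows = pd.DataFrame({"cost": y})
        fit = fit_cost_glm(CostModelSpec("cost", predictors=()), rows)
        assert np.exp(fit.coefficients["const"]) == pytest.approx(y.mean(), rel=1e-8)

    def test_too_few_rows_per_term_rejected(self):
        rows = pd.DataFrame({"cost": [1.0] * 5})
        with pytest.raises(ValueError, match="rows per term"):
            fit_cost_glm(CostModelSpec("cost", predictors=()), rows)

    def test_negative_costs_rejected(self):
        rows = pd.DataFrame({"cost": [-1.0] * 20})
        with pytest.raises(ValueError, match="non-negative"):
            fit_cost_glm(CostModelSpec("cost", predictors=()), rows)

    def test_positive_only_degenerate_level_raises(self):
        rows = pd.DataFrame({
            "stage": ["none"] * 30 + ["5"] * 30,
            "cost": [10.0] * 30 + [0.0] * 30,
        })
        spec = CostModelSpec("cost", predictors=("stage",), zero_handling="positive_only")
        with pytest.raises(ValueError, match="stage"):
            fit_cost_glm(spec, rows)

    def test_duplicated_dataset_same_coefficients_different_aic(self):
        rng = np.random.default_rng(1)
        rows = simulate(800, rng, shape=2.0, coeffs=TRUE_SIMPLE)
        spec = CostModelSpec("cost", predictors=("stage", "sex"))
        fit1 = fit_cost_glm(spec, rows)
        fit2 = fit_cost_glm(spec, pd.concat([rows, rows], ignore_index=True))
        for term, beta in fit1.coefficients.items():
            assert fit2.coefficients[term] == pytest.approx(beta, abs=1e-6)
        assert fit2.aic != pytest.approx(fit1.aic, rel=1e-3)
        assert fit2.n == 2 * fit1.n

    def test_llf_matches_direct_gamma_density_evaluation(self):
        """The fitter's log-likelihood agrees with an independent evaluation
        of the gamma log-density at the fitted mean and dispersion."""
        rng = np.random.default_rng(2)
        rows = simulate(500, rng, shape=2.0, coeffs=TRUE_SIMPLE)
        spec = CostModelSpec("cost", predictors=("stage", "sex"))
        fit = fit_cost_glm(spec, rows)
        mu = predict_costs(fit, rows)
        scale = float(fit.result.scale)  # statsmodels dispersion used in llf
        a = 1.0 / scale
        direct = stats.gamma.logpdf(rows["cost"].to_numpy(), a, scale=mu * scale).sum()
        assert fit.llf == pytest.approx(direct, rel=1e-6)

    def test_coefficient_recovery_bias_below_002(self):
        """Mean estimation error per coefficient over 20 replicates at
        n=20,000, with all five predictors in the truth, stays below 0.02."""
        rng = np.random.default_rng(3)
        truth = dict(TRUE_SIMPLE)
        truth.update({
            "age_band[70-74]": 0.25, "indigenous[True]": 0.20,
            "remoteness[remote]": 0.15,
        })
        predictors = ("stage", "sex", "age_band", "indigenous", "remoteness")
        spec = CostModelSpec("cost", predictors=predictors)
        errors = []
        for _ in range(20):
            rows = simulate(20_000, rng, shape=5.0, coeffs=truth, predictors=predictors)
            fit = fit_cost_glm(spec, rows)
            errors.append({t: fit.coefficients[t] - truth.get(t, 0.0)
                           for t in fit.coefficients})
        mean_err = pd.DataFrame(errors).mean()
        assert (mean_err.abs() < 0.02).all(), mean_err[mean_err.abs() >= 0.02]

    def test_wald_interval_coverage(self):
        """Each coefficient lies inside its 95% Wald interval in ≥ 90% of
        100 replicates at n = 5,000."""
        rng = np.random.default_rng(1234)
        spec = CostModelSpec("cost", predictors=("stage", "sex"))
        hits = None
        for _ in range(100):
            rows = simulate(5_000, rng, shape=2.0, coeffs=TRUE_SIMPLE)
            fit = fit_cost_glm(spec, rows)
            res = fit.result
            names = list(fit.coefficients)
            lo = np.asarray(res.params) - 1.96 * np.asarray(res.bse)
            hi = np.asarray(res.params) + 1.96 * np.asarray(res.bse)
            inside = {
                t: bool(lo[i] <= TRUE_SIMPLE.get(t, 0.0) <= hi[i])
                for i, t in enumerate(names)
            }
            if hits is None:
                hits = {t: 0 for t in names}
            for t, ok in inside.items():
                hits[t] += ok
        coverage = {t: h / 100 for t, h in hits.items()}
        assert all(c >= 0.90 for c in coverage.values()), coverage


# ---------------------------------------------------------------------------
# Model comparison


class TestCompareModels:
    def test_true_model_beats_overparameterised(self):
        """With spurious age-band terms added, AIC ranks the true
        stage+sex model first in ≥ 90% of replicates."""
        rng = np.random.default_rng(4)
        wins = 0
        n_reps = 50
        for _ in range(n_reps):
            rows = simulate(2_000, rng, shape=2.0, coeffs=TRUE_SIMPLE,
                            predictors=("stage", "sex", "age_band"))
            fit_true = fit_cost_glm(CostModelSpec("cost", predictors=("stage", "sex")), rows)
            fit_over = fit_cost_glm(
                CostModelSpec("cost", predictors=("stage", "sex", "age_band")), rows
            )
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ranked = compare_models([fit_over, fit_true])
            wins += ranked[0] is fit_true
        assert wins / n_reps >= 0.90

    def test_single_fit_ranks_itself(self):
        rng = np.random.default_rng(5)
        rows = simulate(500, rng, shape=2.0, coeffs=TRUE_SIMPLE)
        fit = fit_cost_glm(CostModelSpec("cost", predictors=("stage",)), rows)
        assert compare_models([fit]) == [fit]

    def test_differing_n_rejected(self):
        rng = np.random.default_rng(6)
        a = fit_cost_glm(CostModelSpec("cost", predictors=()),
                         simulate(200, rng, 2.0, {"const": 5.0}, ()))
        b = fit_cost_glm(CostModelSpec("cost", predictors=()),
                         simulate(300, rng, 2.0, {"const": 5.0}, ()))
        with pytest.raises(ValueError, match="differing n"):
            compare_models([a, b])

    def test_comparison_table_is_aic_sorted(self):
        rng = np.random.default_rng(7)
        rows = simulate(1_000, rng, shape=2.0, coeffs=TRUE_SIMPLE)
        fits = [
            fit_cost_glm(CostModelSpec("cost", predictors=("stage", "sex")), rows),
            fit_cost_glm(CostModelSpec("cost", predictors=("stage",)), rows),
        ]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = comparison_table(fits)
        assert list(table["aic"]) == sorted(table["aic"])


# ---------------------------------------------------------------------------
# Prediction


class TestPredict:
    def test_training_row_prediction_equals_fitted_values(self):
        rng = np.random.default_rng(8)
        rows = simulate(600, rng, shape=2.0, coeffs=TRUE_SIMPLE)
        fit = fit_cost_glm(CostModelSpec("cost", predictors=("stage", "sex")), rows)
        np.testing.assert_allclose(
            predict_costs(fit, rows), fit.result.fittedvalues, rtol=1e-9
        )

    def test_link_arithmetic_stage_ratio(self):
        rng = np.random.default_rng(9)
        rows = simulate(600, rng, shape=2.0, coeffs=TRUE_SIMPLE)
        fit = fit_cost_glm(CostModelSpec("cost", predictors=("stage", "sex")), rows)
        ref = pd.DataFrame({"stage": ["none"], "sex": ["female"]})
        s5 = pd.DataFrame({"stage": ["5"], "sex": ["female"]})
        ratio = predict_costs(fit, s5)[0] / predict_costs(fit, ref)[0]
        assert ratio == pytest.approx(np.exp(fit.coefficients["stage[5]"]), rel=1e-9)
        assert predict_costs(fit, ref)[0] == pytest.approx(
            np.exp(fit.coefficients["const"]), rel=1e-9
        )

    def test_predictions_strictly_positive(self):
        rng = np.random.default_rng(10)
        rows = simulate(400, rng, shape=2.0, coeffs=TRUE_SIMPLE)
        fit = fit_cost_glm(CostModelSpec("cost", predictors=("stage", "sex")), rows)
        assert (predict_costs(fit, rows) > 0).all()

    def test_unseen_level_named_in_error(self):
        rng = np.random.default_rng(11)
        rows = simulate(400, rng, shape=2.0, coeffs=TRUE_SIMPLE)
        rows = rows[rows["stage"] != "5"]
        fit = fit_cost_glm(CostModelSpec("cost", predictors=("stage", "sex")), rows)
        with pytest.raises(ValueError, match="5"):
            predict_costs(fit, pd.DataFrame({"stage": ["5"], "sex": ["male"]}))

    def test_stratum_prediction_means_match_simulated_means(self):
        """Mean prediction per stage within 3 standard errors of the
        simulated stage mean."""
        rng = np.random.default_rng(12)
        rows = simulate(20_000, rng, shape=2.0, coeffs=TRUE_SIMPLE)
        fit = fit_cost_glm(CostModelSpec("cost", predictors=("stage", "sex")), rows)
        mu = predict_costs(fit, rows)
        for stage in STAGES_WITH_NONE:
            mask = (rows["stage"] == stage).to_numpy()
            obs = rows.loc[mask, "cost"]
            se = obs.std(ddof=1) / np.sqrt(mask.sum())
            assert abs(mu[mask].mean() - obs.mean()) < 3 * se
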