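"""Gamma/log-link GLMs transferring medication, GP and pathology costs.

Per-person medication and GP costs are only observed in the primary-care
extract, and complete community pathology costs only for people who used
the designated provider almost exclusively.  Costs are therefore modelled
on the observed subset — gamma family, log link, main effects of CKD
stage, sex, 5-year age band, indigenous status and remoteness — and the
fitted model is applied to the full cohort.

Estimation is delegated to :mod:`statsmodels` (IRLS maximum likelihood);
this module owns the design-matrix conventions (fixed reference levels),
the zero-cost handling and the model-comparison bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import AGE_BANDS, REMOTENESS, STAGES_WITH_NONE

DEFAULT_PREDICTORS = ("stage", "sex", "age_band", "indigenous", "remoteness")

#: level ladders; the first *observed* level is the reference
_LADDERS = {
    "stage": list(STAGES_WITH_NONE),          # reference: "none"
    "sex": ["female", "male"],                # reference: female
    "age_band": list(AGE_BANDS),              # reference: youngest band
    "indigenous": [False, True],              # reference: non-indigenous
    "remoteness": list(REMOTENESS),           # reference: major cities
}

MIN_ROWS_PER_TERM = 10


@dataclass(frozen=True)
class CostModelSpec:
    """Specification of one cost-transfer model."""

    response: str
    family: str = "gamma"
    link: str = "log"
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    zero_handling: str = "epsilon_shift"
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.family != "gamma" or self.link != "log":
            raise ValueError("only the gamma family with log link is supported")
        if self.zero_handling not in ("epsilon_shift", "positive_only"):
            raise ValueError(f"unknown zero_handling {self.zero_handling!r}")
        if self.zero_handling == "epsilon_shift" and not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        unknown = set(self.predictors) - set(_LADDERS)
        if unknown:
            raise ValueError(f"unknown predictors {sorted(unknown)}")

    @property
    def name(self) -> str:
        return f"{self.response}~{'+'.join(self.predictors) or '1'}|{self.zero_handling}"


@dataclass
class CostModelFit:
    """A fitted gamma/log-link cost model."""

    spec: CostModelSpec
    coefficients: dict[str, float]
    dispersion: float
    aic: float
    bic: float
    llf: float
    n: int
    levels: dict[str, list] = field(default_factory=dict)
    positive_fraction: Optional[dict[str, float]] = None
    result: object = None  # statsmodels GLMResults

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.coefficients.values()))):
            raise ValueError("non-finite coefficients")
        if self.n <= len(self.coefficients):
            raise ValueError("fewer rows than estimated terms")


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Design matrix


def _observed_levels(rows: pd.DataFrame, predictors: Sequence[str]) -> dict[str, list]:
    levels = {}
    for p in predictors:
        seen = set(rows[p])
        levels[p] = [lvl for lvl in _LADDERS[p] if lvl in seen]
        unknown = seen - set(_LADDERS[p])
        if unknown:
            raise ValueError(f"unknown {p} level(s): {sorted(map(str, unknown))}")
    return levels


def _design(rows: pd.DataFrame, levels: dict[str, list]) -> pd.DataFrame:
    cols = {"const": np.ones(len(rows))}
    for p, lvls in levels.items():
        vals = rows[p].to_numpy()
        for lvl in lvls[1:]:  # first observed level is the reference
            cols[f"{p}[{lvl}]"] = (vals == lvl).astype(float)
    return pd.DataFrame(cols, index=rows.index)


# ---------------------------------------------------------------------------
# Subset selection


def select_complete_provider_subset(
    pathology_tests: Iterable[tuple[str, str]] | pd.DataFrame,
    provider_id: str,
    threshold: float = 0.95,
) -> set[str]:
    """Persons whose share of community pathology tests from ``provider_id``
    strictly exceeds ``threshold``.

    ``pathology_tests`` is (person_id, provider_id) pairs or a DataFrame
    with those two columns.  Persons with no pathology tests have an
    undefined share and are excluded.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(pathology_tests, pd.DataFrame):
        df = pathology_tests[["person_id", "provider_id"]]
    else:
        df = pd.DataFrame(list(pathology_tests), columns=["person_id", "provider_id"])
    if df.empty:
        return set()
    share = (
        df.assign(hit=(df["provider_id"] == provider_id).astype(float))
        .groupby("person_id")["hit"]
        .mean()
    )
    return set(share.index[share > threshold])


# ---------------------------------------------------------------------------
# Fitting


def fit_cost_glm(spec: CostModelSpec, rows: pd.DataFrame) -> CostModelFit:
    """Fit a gamma/log-link GLM of ``spec.response`` on the spec's predictors.

    ``rows`` must carry the predictor columns plus a non-negative cost
    column named ``spec.response``.  Zeros are handled per the spec: either
    shifted to ``epsilon`` before fitting, or dropped (``positive_only``),
    in which case the observed positive fraction per CKD stage is retained
    and predictions are rescaled by it.
    """
    y = rows[spec.response].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("costs must be non-negative")

    positive_fraction = None
    if spec.zero_handling == "epsilon_shift":
        fit_rows = rows
        y = np.where(y <= 0, spec.epsilon, y)
    else:
        if "stage" in rows.columns:
            pos = rows.groupby("stage", observed=True)[spec.response].apply(
                lambda s: float((s > 0).mean())
            )
            zero_levels = [str(k) for k, v in pos.items() if v == 0.0]
            if zero_levels:
                raise ValueError(
                    "positive_only fit degenerate: all costs zero for stage "
                    f"level(s) {zero_levels}"
                )
            positive_fraction = dict(pos)
        mask = y > 0
        fit_rows = rows.loc[mask]
        y = y[mask]

    levels = _observed_levels(fit_rows, spec.predictors)
    X = _design(fit_rows, levels)
    n_terms = X.shape[1]
    if len(y) < MIN_ROWS_PER_TERM * n_terms:
        raise ValueError(
            f"need ≥ {MIN_ROWS_PER_TERM} rows per term: "
            f"{len(y)} rows for {n_terms} terms"
        )

    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(maxiter=200, tol=1e-10)
    if not result.converged:
        raise ConvergenceError(
            f"IRLS did not converge for {spec.name} "
            f"(deviance trace: {getattr(result, 'fit_history', {}).get('deviance', [])!r})"
        )

    k = n_terms + 1  # slopes + intercept counted in n_terms; +1 for dispersion
    llf = float(result.llf)
    bic = -2.0 * llf + k * np.log(len(y))
    aic = -2.0 * llf + 2.0 * k
    return CostModelFit(
        spec=spec,
        coefficients=dict(zip(X.columns, map(float, result.params))),
        dispersion=float(result.pearson_chi2 / result.df_resid),
        aic=aic,
        bic=bic,
        llf=llf,
        n=int(len(y)),
        levels=levels,
        positive_fraction=positive_fraction,
        result=result,
    )


def compare_models(fits: Sequence[CostModelFit]) -> list[CostModelFit]:
    """Rank candidate fits by AIC (BIC reported alongside).

    All fits must be estimated on the same rows (same n).  When AIC and
    BIC disagree on the best model a warning is emitted and AIC wins.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits estimated on differing n: {sorted(ns)}")
    by_aic = sorted(fits, key=lambda f: (f.aic, f.spec.name))
    by_bic = sorted(fits, key=lambda f: (f.bic, f.spec.name))
    if by_aic[0] is not by_bic[0]:
        warnings.warn(
            f"AIC prefers {by_aic[0].spec.name} but BIC prefers "
            f"{by_bic[0].spec.name}; ranking by AIC",
            stacklevel=2,
        )
    return by_aic


def comparison_table(fits: Sequence[CostModelFit]) -> pd.DataFrame:
    """Model-comparison table (AIC-ranked) for reporting."""
    ranked = compare_models(fits)
    return pd.DataFrame(
        {
            "model": [f.spec.name for f in ranked],
            "n": [f.n for f in ranked],
            "aic": [f.aic for f in ranked],
            "bic": [f.bic for f in ranked],
            "dispersion": [f.dispersion for f in ranked],
        }
    )


def predict_costs(fit: CostModelFit, cohort: pd.DataFrame) -> np.ndarray:
    """Predicted cost per cohort row: exp(linear predictor), strictly positive.

    Every predictor level in ``cohort`` must have been seen in training;
    an unseen level raises with the level named.  Under ``positive_only``
    zero handling, predictions are scaled by the training positive
    fraction of the row's CKD stage.
    """
    for p, lvls in fit.levels.items():
        unseen = set(cohort[p]) - set(lvls)
        if unseen:
            raise ValueError(
                f"unseen {p} level(s) at prediction: {sorted(map(str, unseen))}"
            )
    X = _design(cohort, fit.levels)
    beta = np.array([fit.coefficients[c] for c in X.columns])
    mu = np.exp(X.to_numpy() @ beta)
    if fit.positive_fraction is not None:
        frac = cohort["stage"].map(fit.positive_fraction).to_numpy(dtype=float)
        mu = mu * frac
    return mu
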