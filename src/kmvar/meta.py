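"""Weighted random-intercept meta-regression of log(SD) of time to death.

Observational units are trial arms.  The primary model is

    y_ij = b0 + b1 * trt_ij + b2 * logMean_ij + u_i + e_ij,
    u_i ~ N(0, tau^2),   e_ij ~ N(0, v_ij),

where ``y_ij`` is an arm's log(SD) of time to death, ``trt`` is 1 for verum
and 0 for placebo, ``logMean`` adjusts for the location of the time-to-death
distribution, ``u_i`` is a trial random intercept capturing the correlation
of the two arms of a trial, and the sampling variances ``v_ij = Var(log SD)``
are treated as known (each observation is weighted by ``1 / v_ij``, the
meta-analytic convention).  ``b1 = 0`` means equal outcome variability under
verum and placebo — no signal of treatment-effect heterogeneity and hence no
potential for precision treatment selection.

``tau^2`` is estimated by restricted maximum likelihood on a nonnegative
grid-refined one-dimensional profile; fixed effects are generalized least
squares at the optimum with Wald (z) 95% intervals.

Interaction screens extend the primary model by a clinical predictor's main
effect and its interaction with treatment, one predictor at a time
(trial-level predictors; ecological, not individual-level, adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .errors import InputError, SingularDesignError
from .weibull import ArmVariability, arms_to_frame

__all__ = [
    "TrialCovariateRecord",
    "MetaRegressionFit",
    "CONTINUOUS_PREDICTORS",
    "PREDICTORS",
    "DRUG_CLASSES",
    "fit_primary",
    "fit_interaction",
    "screen_all_predictors",
    "subgroup_fit",
    "covariates_to_frame",
]

logger = logging.getLogger(__name__)

DRUG_CLASSES = ("DPP-4", "GLP-1", "SGLT2")

#: screen order: baseline clinical means, follow-up, calendar year, drug class
CONTINUOUS_PREDICTORS = [
    "mean_age",
    "pct_male",
    "mean_bmi",
    "mean_hba1c",
    "mean_duration",
    "mean_egfr",
    "mean_sbp",
    "mean_chol",
    "mean_trig",
    "median_follow_up",
    "year",
]
PREDICTORS = CONTINUOUS_PREDICTORS + ["drug_class"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class TrialCovariateRecord:
    """Trial-level covariates (baseline summary measures); any may be missing."""

    trial_id: str
    drug_class: str | None = None
    median_follow_up: float | None = None
    year: int | None = None
    mean_age: float | None = None
    pct_male: float | None = None
    mean_bmi: float | None = None
    mean_hba1c: float | None = None
    mean_duration: float | None = None
    mean_egfr: float | None = None
    mean_sbp: float | None = None
    mean_chol: float | None = None
    mean_trig: float | None = None

    def __post_init__(self):
        if self.drug_class is not None and self.drug_class not in DRUG_CLASSES:
            raise InputError(f"drug_class must be one of {DRUG_CLASSES}")
        if self.pct_male is not None and not 0 <= self.pct_male <= 100:
            raise InputError("pct_male must lie in [0, 100]")


def covariates_to_frame(covariates) -> pd.DataFrame:
    """Normalize covariate input (records, dicts or DataFrame) to a frame."""
    if isinstance(covariates, pd.DataFrame):
        df = covariates.copy()
    else:
        rows = []
        for c in covariates:
            if isinstance(c, TrialCovariateRecord):
                rows.append({f.name: getattr(c, f.name) for f in dc_fields(c)})
            else:
                rows.append(dict(c))
        df = pd.DataFrame(rows)
    if "trial_id" not in df.columns:
        raise InputError("covariates must carry a trial_id column")
    df["trial_id"] = df["trial_id"].astype(str)
    return df


@dataclass(frozen=True)
class MetaRegressionFit:
    """Fixed-effect estimates with Wald inference plus random-intercept variance."""

    coefficients: dict
    se: dict
    ci95: dict
    tau2: float
    n_arms: int
    n_trials: int
    converged: bool = True
    tau2_at_bound: bool = False
    warnings: tuple = ()
    dropped_trials: int = 0
    predictor: str | None = None

    def summary_frame(self, model: str = "primary") -> pd.DataFrame:
        rows = [
            {
                "model": model,
                "term": term,
                "estimate": self.coefficients[term],
                "se": self.se[term],
                "ci_low": self.ci95[term][0],
                "ci_high": self.ci95[term][1],
                "tau2": self.tau2,
                "n_arms": self.n_arms,
                "n_trials": self.n_trials,
            }
            for term in self.coefficients
        ]
        return pd.DataFrame(rows)


def _reml_neg_loglik(tau2, y, X, v, Z):
    """Negative REML log-likelihood and the GLS pieces at a given tau^2."""
    V = np.diag(v) + tau2 * (Z @ Z.T)
    cho = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
    vinv_x = cho_solve(cho, X)
    vinv_y = cho_solve(cho, y)
    A = X.T @ vinv_x
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        raise SingularDesignError("design matrix is singular under the working covariance")
    beta = np.linalg.solve(A, X.T @ vinv_y)
    r = y - X @ beta
    quad = float(r @ cho_solve(cho, r))
    nll = 0.5 * (logdet_v + logdet_a + quad)
    return nll, beta, A


def _check_design(X: np.ndarray, names: list[str]):
    # scale columns before the rank check so units do not mask deficiency
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise SingularDesignError(f"column {names[int(np.argmin(norms))]!r} is all zero")
    if np.linalg.matrix_rank(X / norms, tol=1e-10) < X.shape[1]:
        raise SingularDesignError(
            f"design with columns {names} is rank deficient "
            "(e.g. a constant or aliased predictor)"
        )


def _fit_weighted_mixed(
    y: np.ndarray,
    X: np.ndarray,
    v: np.ndarray,
    trial_ids: np.ndarray,
    names: list[str],
    tau2: float | None = None,
    **fit_meta,
) -> MetaRegressionFit:
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    v = np.asarray(v, float)
    if np.any(v <= 0):
        raise InputError("sampling variances must be positive")
    if X.shape[0] != len(y) or X.shape[0] <= X.shape[1]:
        raise InputError("more coefficients than observations")
    _check_design(X, names)
    codes, uniques = pd.factorize(trial_ids)
    Z = np.zeros((len(y), len(uniques)))
    Z[np.arange(len(y)), codes] = 1.0

    tau2_at_bound = False
    converged = True
    if tau2 is None:
        spread = float(np.var(y))
        hi = max(10.0 * spread, 10.0 * float(np.median(v)), 1e-3)
        grid = np.concatenate([[0.0], np.geomspace(hi * 1e-8, hi, 80)])
        nlls = np.array([_reml_neg_loglik(g, y, X, v, Z)[0] for g in grid])
        best = int(np.argmin(nlls))
        candidates = {float(grid[k]): float(nlls[k]) for k in range(len(grid))}
        lo_b = grid[max(best - 1, 0)]
        hi_b = grid[min(best + 1, len(grid) - 1)]
        if hi_b > lo_b:
            res = minimize_scalar(
                lambda g: _reml_neg_loglik(g, y, X, v, Z)[0],
                bounds=(lo_b, hi_b),
                method="bounded",
                options={"xatol": 1e-12},
            )
            candidates[float(res.x)] = float(res.fun)
            converged = bool(res.success)
        tau2 = min(candidates, key=candidates.get)  # argmax REML over all candidates
        tau2_at_bound = tau2 >= grid[-1] * (1 - 1e-9)
    elif tau2 < 0:
        raise InputError("tau2 must be nonnegative")

    _, beta, A = _reml_neg_loglik(tau2, y, X, v, Z)
    cov_beta = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    coef = dict(zip(names, beta.tolist()))
    se_d = dict(zip(names, se.tolist()))
    ci = {k: (coef[k] - _Z95 * se_d[k], coef[k] + _Z95 * se_d[k]) for k in names}
    warnings = tuple(fit_meta.pop("warnings", ()))
    if tau2_at_bound:
        warnings += ("tau2 estimate hit the upper search bound",)
    return MetaRegressionFit(
        coefficients=coef,
        se=se_d,
        ci95=ci,
        tau2=float(tau2),
        n_arms=len(y),
        n_trials=len(uniques),
        converged=converged,
        tau2_at_bound=tau2_at_bound,
        warnings=warnings,
        **fit_meta,
    )


def _primary_design(df: pd.DataFrame):
    y = df["log_sd"].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(df)), df["treatment"].to_numpy(float), df["log_mean"].to_numpy(float)]
    )
    return y, X, df["var_log_sd"].to_numpy(float), df["trial_id"].to_numpy()


def _validate_paired(df: pd.DataFrame, min_trials: int = 2):
    by_trial = df.groupby("trial_id")["treatment"].agg(lambda s: set(s))
    if len(by_trial) < min_trials:
        raise InputError(f"need at least {min_trials} trials (got {len(by_trial)})")
    unpaired = [t for t, arms in by_trial.items() if arms != {0, 1}]
    if unpaired:
        raise InputError(f"trials without both arms: {unpaired}")


def fit_primary(arms: list[ArmVariability], tau2: float | None = None) -> MetaRegressionFit:
    """Fit the primary model: log(SD) ~ treatment + log(Mean) + (1 | trial).

    ``tau2=None`` estimates the random-intercept variance by REML; passing a
    fixed value (e.g. 0) skips the profile, which yields the plain weighted
    GLS solution.
    """
    df = arms_to_frame(list(arms))
    _validate_paired(df)
    y, X, v, tid = _primary_design(df)
    return _fit_weighted_mixed(
        y, X, v, tid, ["intercept", "treatment", "log_mean"], tau2=tau2
    )


def fit_interaction(
    arms: list[ArmVariability],
    covariates,
    predictor: str,
    tau2: float | None = None,
) -> MetaRegressionFit:
    """Primary model extended by a predictor main effect and treatment interaction.

    Continuous predictors are centered at the mean over included arms; trials
    missing the predictor are dropped (complete-case, count logged).  The
    drug class enters as two indicator contrasts with DPP-4 as reference.
    """
    if predictor not in PREDICTORS:
        raise InputError(f"unknown predictor {predictor!r}; expected one of {PREDICTORS}")
    cov = covariates_to_frame(covariates)
    if predictor not in cov.columns:
        raise InputError(f"covariates lack a {predictor!r} column")
    df = arms_to_frame(list(arms)).merge(
        cov[["trial_id", predictor]], on="trial_id", how="left"
    )
    miss = df[predictor].isna()
    if miss.all():
        raise InputError(f"predictor {predictor!r} is missing for every trial")
    dropped = df.loc[miss, "trial_id"].nunique()
    if dropped:
        logger.info("predictor %s: dropping %d trial(s) with missing values", predictor, dropped)
    df = df[~miss]
    if df["trial_id"].nunique() < 3:
        raise InputError(
            f"fewer than 3 trials remain with non-missing {predictor!r}"
        )
    _validate_paired(df)
    y, X, v, tid = _primary_design(df)
    trt = df["treatment"].to_numpy(float)
    names = ["intercept", "treatment", "log_mean"]
    if predictor == "drug_class":
        present = [c for c in DRUG_CLASSES if (df[predictor] == c).any()]
        if len(present) < 2:
            raise SingularDesignError("drug_class is constant across the included trials")
        for cls in present[1:]:  # first present class is the reference
            ind = (df[predictor] == cls).to_numpy(float)
            X = np.column_stack([X, ind])
            names.append(f"drug_class[{cls}]")
        for cls in present[1:]:
            ind = (df[predictor] == cls).to_numpy(float)
            X = np.column_stack([X, trt * ind])
            names.append(f"treatment:drug_class[{cls}]")
    else:
        x = df[predictor].to_numpy(float)
        xc = x - x.mean()
        X = np.column_stack([X, xc, trt * xc])
        names.extend([predictor, f"treatment:{predictor}"])
    return _fit_weighted_mixed(
        y, X, v, tid, names, tau2=tau2, predictor=predictor, dropped_trials=int(dropped)
    )


def interaction_terms(fit: MetaRegressionFit) -> list[str]:
    return [t for t in fit.coefficients if t.startswith("treatment:")]


def screen_all_predictors(arms: list[ArmVariability], covariates) -> pd.DataFrame:
    """Run the interaction model for every predictor; failures are recorded rows.

    Returns one row per treatment-interaction contrast in the fixed screen
    order, with estimate, SE, 95% CI, tau^2 and the numbers of arms/trials
    actually used.
    """
    rows = []
    for predictor in PREDICTORS:
        try:
            fit = fit_interaction(arms, covariates, predictor)
        except (InputError, SingularDesignError) as exc:
            rows.append(
                {
                    "predictor": predictor,
                    "term": None,
                    "estimate": np.nan,
                    "se": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "tau2": np.nan,
                    "n_arms": 0,
                    "n_trials": 0,
                    "error": str(exc),
                }
            )
            continue
        for term in interaction_terms(fit):
            rows.append(
                {
                    "predictor": predictor,
                    "term": term,
                    "estimate": fit.coefficients[term],
                    "se": fit.se[term],
                    "ci_low": fit.ci95[term][0],
                    "ci_high": fit.ci95[term][1],
                    "tau2": fit.tau2,
                    "n_arms": fit.n_arms,
                    "n_trials": fit.n_trials,
                    "error": "",
                }
            )
    return pd.DataFrame(rows)


def subgroup_fit(
    arms: list[ArmVariability], covariates, drug_class: str, tau2: float | None = None
) -> MetaRegressionFit:
    """Primary model restricted to the trials of one drug class.

    Flags small subgroups (six arms or fewer) whose standard errors should
    not be over-interpreted.
    """
    if drug_class not in DRUG_CLASSES:
        raise InputError(f"drug_class must be one of {DRUG_CLASSES}")
    cov = covariates_to_frame(covariates)
    if "drug_class" not in cov.columns:
        raise InputError("covariates lack a drug_class column")
    keep = set(cov.loc[cov["drug_class"] == drug_class, "trial_id"])
    sub = [a for a in arms if a.trial_id in keep]
    df = arms_to_frame(sub) if sub else pd.DataFrame(columns=["trial_id"])
    if df.empty or df["trial_id"].nunique() < 2:
        raise InputError(f"need at least 2 trials of class {drug_class}")
    _validate_paired(df)
    y, X, v, tid = _primary_design(df)
    warnings = ()
    if len(y) <= 6:
        warnings = (
            f"only {len(y)} arms in the {drug_class} subgroup; "
            "standard errors may be unreliable",
        )
    return _fit_weighted_mixed(
        y, X, v, tid, ["intercept", "treatment", "log_mean"],
        tau2=tau2, warnings=warnings, predictor=drug_class,
    )
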