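"""Weighted random-intercept meta-regression: oracles, invariances, screens."""

import json

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import kmvar
from kmvar.errors import InputError, SingularDesignError
from kmvar.meta import (
    PREDICTORS,
    _fit_weighted_mixed,
    _reml_neg_loglik,
    covariates_to_frame,
    fit_interaction,
    fit_primary,
    screen_all_predictors,
    subgroup_fit,
)
from kmvar.weibull import ArmVariability


def make_arms(y, log_means, v, trial_ids=None):
    """Arm list from vectors: even index placebo, odd index verum per trial."""
    arms = []
    n = len(y)
    for i in range(n):
        arms.append(
            ArmVariability(
                trial_id=trial_ids[i] if trial_ids else f"t{i // 2}",
                treatment=i % 2,
                log_sd=float(y[i]),
                log_mean=float(log_means[i]),
                var_log_sd=float(v[i]),
                n=1000,
                n_events=100,
            )
        )
    return arms


def synthetic_meta_data(seed=0, n_trials=8, beta=(5.0, -0.05, 0.3), tau=0.1):
    """Arm-level data drawn exactly from the meta-regression model."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_trials):
        lm = rng.uniform(5.2, 6.2)
        b = rng.normal(0, tau)
        for trt in (0, 1):
            v = rng.uniform(0.002, 0.006)
            y = beta[0] + beta[1] * trt + beta[2] * lm + b + rng.normal(0, np.sqrt(v))
            rows.append((f"t{i}", trt, y, lm, v))
    return rows


class TestPrimaryFit:
    def test_symmetric_arms_give_zero_treatment_effect(self):
        # same log_sd and log_mean in both arms of every trial
        y = [5.2, 5.2, 5.6, 5.6, 5.9, 5.9]
        lm = [5.5, 5.5, 5.8, 5.8, 6.1, 6.1]
        arms = make_arms(y, lm, [0.01] * 6)
        fit = fit_primary(arms)
        assert abs(fit.coefficients["treatment"]) < 1e-10

    def test_gls_limit_matches_normal_equations(self):
        rows = synthetic_meta_data(seed=3)
        y = np.array([r[2] for r in rows])
        lm = np.array([r[3] for r in rows])
        arms = make_arms(y, lm, [0.004] * len(rows), [r[0] for r in rows])
        fit = fit_primary(arms, tau2=0.0)
        X = np.column_stack([np.ones(len(y)), np.arange(len(y)) % 2, lm])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # equal weights cancel
        est = np.array(
            [fit.coefficients[k] for k in ("intercept", "treatment", "log_mean")]
        )
        assert np.allclose(est, beta, atol=1e-8)

    def test_estimates_invariant_to_ordering_and_labels(self):
        rows = synthetic_meta_data(seed=4)
        y = [r[2] for r in rows]
        lm = [r[3] for r in rows]
        v = [r[4] for r in rows]
        ids = [r[0] for r in rows]
        arms = make_arms(y, lm, v, ids)
        fit1 = fit_primary(arms)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(arms))
        relabel = {f"t{i}": f"study_{chr(65 + i)}" for i in range(8)}
        arms2 = [
            ArmVariability(
                trial_id=relabel[a.trial_id],
                treatment=a.treatment,
                log_sd=a.log_sd,
                log_mean=a.log_mean,
                var_log_sd=a.var_log_sd,
                n=a.n,
                n_events=a.n_events,
            )
            for a in (arms[p] for p in perm)
        ]
        fit2 = fit_primary(arms2)
        for k in fit1.coefficients:
            assert abs(fit1.coefficients[k] - fit2.coefficients[k]) < 1e-9
        assert abs(fit1.tau2 - fit2.tau2) < 1e-7

    def test_constant_log_mean_is_singular(self):
        y = [5.2, 5.1, 5.6, 5.5, 5.9, 5.8]
        arms = make_arms(y, [5.5] * 6, [0.01] * 6)
        with pytest.raises(SingularDesignError):
            fit_primary(arms)

    def test_requires_paired_trials(self):
        arms = make_arms([5.0, 5.1], [5.5, 5.6], [0.01] * 2)  # one trial only
        with pytest.raises(InputError):
            fit_primary(arms)
        lone = [
            ArmVariability("a", 0, 5.0, 5.5, 0.01, 10, 5),
            ArmVariability("a", 1, 5.1, 5.5, 0.01, 10, 5),
            ArmVariability("b", 0, 5.2, 5.7, 0.01, 10, 5),
        ]
        with pytest.raises(InputError, match="both arms"):
            fit_primary(lone)

    def test_returned_tau2_attains_grid_maximum(self):
        rows = synthetic_meta_data(seed=5, tau=0.15)
        y = np.array([r[2] for r in rows])
        lm = np.array([r[3] for r in rows])
        v = np.array([r[4] for r in rows])
        ids = [r[0] for r in rows]
        arms = make_arms(y, lm, v, ids)
        fit = fit_primary(arms)
        X = np.column_stack([np.ones(len(y)), np.arange(len(y)) % 2, lm])
        codes, uniq = pd.factorize(np.array(ids))
        Z = np.zeros((len(y), len(uniq)))
        Z[np.arange(len(y)), codes] = 1.0
        nll_hat = _reml_neg_loglik(fit.tau2, y, X, v, Z)[0]
        for g in np.concatenate([[0.0], np.geomspace(1e-8, 1.0, 60)]):
            assert nll_hat <= _reml_neg_loglik(g, y, X, v, Z)[0] + 1e-9

    def test_ci_is_estimate_plus_minus_z_se(self):
        rows = synthetic_meta_data(seed=6)
        arms = make_arms(
            [r[2] for r in rows], [r[3] for r in rows], [r[4] for r in rows],
            [r[0] for r in rows],
        )
        fit = fit_primary(arms)
        for k in fit.coefficients:
            lo, hi = fit.ci95[k]
            assert np.isclose(hi - fit.coefficients[k], 1.959963984540054 * fit.se[k])
            assert np.isclose(fit.coefficients[k] - lo, 1.959963984540054 * fit.se[k])

    def test_coverage_on_correctly_specified_meta_level_data(self):
        # y drawn exactly from the linear mixed model with known v and fixed
        # covariates: the Wald interval for the treatment effect should hold
        # its nominal level up to small-sample REML noise
        R = 300
        hits = 0
        for r in range(R):
            rows = synthetic_meta_data(seed=1000 + r, n_trials=10, tau=0.05)
            arms = make_arms(
                [x[2] for x in rows], [x[3] for x in rows], [x[4] for x in rows],
                [x[0] for x in rows],
            )
            fit = fit_primary(arms)
            lo, hi = fit.ci95["treatment"]
            hits += lo <= -0.05 <= hi
        assert 0.90 <= hits / R <= 0.98


class TestMetaforCrossCheck:
    def test_reml_matches_metafor(self, tmp_path):
        rows = synthetic_meta_data(seed=7, n_trials=8, tau=0.12)
        df = pd.DataFrame(rows, columns=["trial", "trt", "y", "lm", "v"])
        csv = tmp_path / "arms.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages({{library(metafor); library(jsonlite)}})
                d <- read.csv("{csv}")
                res <- rma.mv(yi = y, V = v, mods = ~ trt + lm,
                              random = ~ 1 | trial, data = d, method = "REML")
                cat(toJSON(list(beta = as.numeric(res$beta),
                                se = as.numeric(res$se),
                                tau2 = res$sigma2), digits = 12))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        arms = make_arms(df["y"], df["lm"], df["v"], list(df["trial"]))
        fit = fit_primary(arms)
        mine = [fit.coefficients[k] for k in ("intercept", "treatment", "log_mean")]
        assert np.allclose(mine, ref["beta"], atol=1e-4)
        assert np.allclose(
            [fit.se[k] for k in ("intercept", "treatment", "log_mean")],
            ref["se"],
            atol=1e-4,
        )
        assert abs(fit.tau2 - ref["tau2"][0]) < 1e-4


def portfolio_covariates(trials):
    return pd.DataFrame([t.covariates for t in trials])


@pytest.fixture(scope="module")
def fitted_portfolio():
    truth = kmvar.PortfolioTruth(n_trials=6, n_range=(800, 1200), seed=30)
    trials = kmvar.simulate_portfolio(truth)
    from conftest import portfolio_to_arms

    return portfolio_to_arms(trials), portfolio_covariates(trials)


class TestInteractions:
    def test_constant_predictor_is_singular(self, fitted_portfolio):
        arms, cov = fitted_portfolio
        cov = cov.copy()
        cov["mean_age"] = 64.0
        with pytest.raises(SingularDesignError):
            fit_interaction(arms, cov, "mean_age")

    def test_all_missing_predictor_rejected(self, fitted_portfolio):
        arms, cov = fitted_portfolio
        cov = cov.copy()
        cov["mean_chol"] = np.nan
        with pytest.raises(InputError, match="missing"):
            fit_interaction(arms, cov, "mean_chol")

    def test_partially_missing_predictor_drops_trials(self, fitted_portfolio):
        arms, cov = fitted_portfolio
        cov = cov.copy()
        cov.loc[cov.index[:3], "mean_chol"] = np.nan  # as in published tables
        fit = fit_interaction(arms, cov, "mean_chol")
        assert fit.dropped_trials == 3
        assert fit.n_trials == len(cov) - 3

    def test_unknown_predictor_rejected(self, fitted_portfolio):
        arms, cov = fitted_portfolio
        with pytest.raises(InputError):
            fit_interaction(arms, cov, "shoe_size")

    def test_drug_class_contrasts_near_zero_without_built_in_effect(
        self, fitted_portfolio
    ):
        arms, cov = fitted_portfolio
        fit = fit_interaction(arms, cov, "drug_class")
        for term in ("treatment:drug_class[GLP-1]", "treatment:drug_class[SGLT2]"):
            lo, hi = fit.ci95[term]
            assert lo <= 0 <= hi

    def test_screen_order_and_error_recording(self, fitted_portfolio):
        arms, cov = fitted_portfolio
        cov = cov.copy()
        cov["mean_trig"] = np.nan  # unusable predictor recorded, not fatal
        table = screen_all_predictors(arms, cov)
        assert list(table["predictor"].drop_duplicates()) == PREDICTORS
        bad = table[table["predictor"] == "mean_trig"]
        assert bad["error"].iloc[0] != ""
        good = table[(table["predictor"] != "mean_trig") & (table["term"].notna())]
        assert (good["n_trials"] == 6).all()


class TestSubgroup:
    def test_identical_arms_give_zero(self):
        y = [5.2, 5.2, 5.6, 5.6]
        lm = [5.5, 5.5, 5.9, 5.9]
        arms = make_arms(y, lm, [0.01] * 4)
        cov = pd.DataFrame({"trial_id": ["t0", "t1"], "drug_class": ["GLP-1", "GLP-1"]})
        fit = subgroup_fit(arms, cov, "GLP-1")
        assert abs(fit.coefficients["treatment"]) < 1e-10

    def test_small_subgroup_flagged(self):
        rows = synthetic_meta_data(seed=9, n_trials=3)
        arms = make_arms(
            [r[2] for r in rows], [r[3] for r in rows], [r[4] for r in rows],
            [r[0] for r in rows],
        )
        cov = pd.DataFrame(
            {"trial_id": ["t0", "t1", "t2"], "drug_class": ["SGLT2"] * 3}
        )
        fit = subgroup_fit(arms, cov, "SGLT2")
        assert fit.n_arms == 6
        assert any("unreliable" in w for w in fit.warnings)

    def test_single_trial_class_rejected(self):
        rows = synthetic_meta_data(seed=10, n_trials=4)
        arms = make_arms(
            [r[2] for r in rows], [r[3] for r in rows], [r[4] for r in rows],
            [r[0] for r in rows],
        )
        cov = pd.DataFrame(
            {
                "trial_id": [f"t{i}" for i in range(4)],
                "drug_class": ["DPP-4", "GLP-1", "GLP-1", "GLP-1"],
            }
        )
        with pytest.raises(InputError):
            subgroup_fit(arms, cov, "DPP-4")

    def test_records_normalized_from_dataclasses(self):
        recs = [
            kmvar.TrialCovariateRecord(trial_id="a", drug_class="GLP-1", mean_hba1c=8.1),
            kmvar.TrialCovariateRecord(trial_id="b", drug_class="SGLT2"),
        ]
        df = covariates_to_frame(recs)
        assert list(df["trial_id"]) == ["a", "b"]
        assert np.isnan(df.loc[1, "mean_hba1c"])
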