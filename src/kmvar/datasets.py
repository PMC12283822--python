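"""Bundled reference data.

``load_cvot_arms`` returns the published arm-level summary of the ten large
placebo-controlled cardiovascular outcome trials (CVOTs) of glucose-lowering
drugs that the analysis pipeline targets: per-arm death and observation
counts, median follow-up, and baseline covariate means as printed in the
trial reports.  Missing cells (lipids for some trials, disease duration for
one) are left empty.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cvot_arms", "cvot_trial_covariates"]


def load_cvot_arms() -> pd.DataFrame:
    """Arm-level summary table of the ten included CVOTs (one row per arm)."""
    with resources.files("kmvar.data").joinpath("cvot_arms.csv").open() as fh:
        return pd.read_csv(fh)


def cvot_trial_covariates(arms: pd.DataFrame | None = None) -> pd.DataFrame:
    """Trial-level covariate records, averaging the two arms of each trial.

    The interaction screen uses trial-level predictors; the published
    baseline tables report them per arm, and the arms of a randomized trial
    are near-identical at baseline, so the arm mean is used.
    """
    if arms is None:
        arms = load_cvot_arms()
    value_cols = [
        "median_follow_up",
        "year",
        "mean_age",
        "pct_male",
        "mean_bmi",
        "mean_hba1c",
        "mean_duration",
        "mean_egfr",
        "mean_sbp",
        "mean_chol",
        "mean_trig",
    ]
    grouped = arms.groupby("trial_id", sort=False)
    out = grouped[value_cols].mean()
    out["year"] = out["year"].round().astype("Int64")
    out.insert(0, "drug_class", grouped["drug_class"].first())
    return out.reset_index()
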