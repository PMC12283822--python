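"""Synthetic two-arm cardiovascular-outcome-trial (CVOT) generator.

The generator produces portfolios of placebo-controlled trials with a known
ground truth for the quantity the downstream analysis estimates: the
difference in log(SD) of time to death between verum (active) and placebo
arms, with trial-level random intercepts on log(SD).

Generative structure per trial ``i`` (arms ``j``: 0 = placebo, 1 = verum):

* a trial base level ``base_i ~ U(base_log_sd_range)`` and random intercept
  ``b_i ~ N(0, tau^2)``;
* a trial-level log mean time to death
  ``logMean_i = (base_i - intercept) / beta_log_mean`` — exogenous, so the
  downstream adjustment model is correctly specified;
* target ``logSD_ij = intercept + beta_1i * trt_j + beta_log_mean * logMean_i + b_i``
  where ``beta_1i`` is ``beta_treatment`` plus an optional built-in
  treatment-by-predictor interaction;
* Weibull shape and scale solved jointly from the (mean, SD) targets;
* event times drawn Weibull, censored at the earlier of an exponential
  dropout time and the administrative follow-up cutoff.

Rendering (:func:`render_km`) turns simulated records into exactly the input
the reconstruction consumes — product-limit step coordinates and a
number-at-risk table — and :func:`perturb_digitization` emulates digitization
pixel error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression

from .errors import InputError, ParameterError
from .reconstruct import IPD, RiskTable, SurvivalCurve, km_estimate
from .weibull import weibull_parameters_for_moments

__all__ = [
    "ArmTruth",
    "PortfolioTruth",
    "SimulatedTrial",
    "simulate_arm",
    "simulate_portfolio",
    "render_km",
    "default_risk_times",
    "perturb_digitization",
]

#: uniform sampling ranges for trial-level covariates, patterned on the
#: spread observed across published CVOT baseline tables
DEFAULT_COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "median_follow_up": (19.4, 65.4),
    "year": (2013, 2019),
    "mean_age": (61.0, 66.2),
    "pct_male": (53.4, 72.0),
    "mean_bmi": (28.7, 32.5),
    "mean_hba1c": (7.2, 8.7),
    "mean_duration": (7.1, 16.0),
    "mean_egfr": (54.5, 85.4),
    "mean_sbp": (135.0, 140.6),
    "mean_chol": (153.9, 180.9),
    "mean_trig": (141.6, 198.8),
}

_DRUG_CLASSES = ("DPP-4", "GLP-1", "SGLT2")


@dataclass(frozen=True)
class ArmTruth:
    """Ground-truth generating parameters of one trial arm."""

    shape: float  # Weibull k
    scale: float  # Weibull lambda, months
    max_follow_up: float  # administrative censoring time, months
    dropout_rate: float = 0.0  # exponential random-censoring hazard per month
    n: int = 1000

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ParameterError("shape and scale must be positive")
        if self.max_follow_up <= 0:
            raise ParameterError("max_follow_up must be positive")
        if self.dropout_rate < 0:
            raise ParameterError("dropout_rate must be nonnegative")
        if int(self.n) < 1:
            raise ParameterError("n must be at least 1")


@dataclass(frozen=True)
class PortfolioTruth:
    """Ground truth for a portfolio of two-arm trials.

    ``beta_treatment`` is the true verum-minus-placebo difference in log(SD)
    and ``tau`` the SD of the trial random intercepts on log(SD); both are the
    quantities the meta-regression estimates.
    """

    n_trials: int = 10
    beta_treatment: float = -0.036
    tau: float = 0.05
    base_log_sd_range: tuple[float, float] = (5.0, 6.0)
    intercept: float = -0.18
    beta_log_mean: float = 1.0
    n_range: tuple[int, int] = (2200, 8600)
    follow_up_range: tuple[float, float] = (24.0, 66.0)
    dropout_rate: float = 0.002
    interaction_predictor: str | None = None
    interaction_slope: float = 0.0
    interaction_center: float = 0.0
    covariate_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 2:
            raise ParameterError("n_trials must be at least 2")
        if self.tau < 0:
            raise ParameterError("tau must be nonnegative")
        if self.base_log_sd_range[0] > self.base_log_sd_range[1]:
            raise ParameterError("base_log_sd_range must be a nonempty interval")
        if self.interaction_predictor is not None and (
            self.interaction_predictor not in self.covariate_ranges
        ):
            raise ParameterError(
                f"unknown interaction predictor {self.interaction_predictor!r}"
            )


@dataclass(frozen=True)
class SimulatedTrial:
    trial_id: str
    placebo: tuple[ArmTruth, IPD]
    verum: tuple[ArmTruth, IPD]
    covariates: dict


def simulate_arm(truth: ArmTruth, seed) -> IPD:
    """Draw one arm: time = min(Weibull event, dropout, follow-up cutoff)."""
    rng = np.random.default_rng(seed)
    n = int(truth.n)
    t_event = truth.scale * rng.weibull(truth.shape, n)
    if truth.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / truth.dropout_rate, n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, truth.max_follow_up)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)  # guard the measure-zero exact-zero draw
    return IPD(time, event)


def _arm_truth_for_targets(
    log_mean: float, log_sd: float, max_follow_up: float, dropout: float, n: int
) -> ArmTruth:
    shape, scale = weibull_parameters_for_moments(math.exp(log_mean), math.exp(log_sd))
    return ArmTruth(
        shape=shape, scale=scale, max_follow_up=max_follow_up,
        dropout_rate=dropout, n=n,
    )


def simulate_portfolio(truth: PortfolioTruth) -> list[SimulatedTrial]:
    """Generate ``n_trials`` two-arm trials; reproducible under ``truth.seed``."""
    rng = np.random.default_rng(truth.seed)
    ss = np.random.SeedSequence(truth.seed).spawn(truth.n_trials * 2)
    trials = []
    for i in range(truth.n_trials):
        covs = {"drug_class": _DRUG_CLASSES[i % 3]}
        for name, (lo, hi) in truth.covariate_ranges.items():
            val = rng.uniform(lo, hi)
            covs[name] = int(round(val)) if name == "year" else float(val)

        base = rng.uniform(*truth.base_log_sd_range)
        b_i = rng.normal(0.0, truth.tau) if truth.tau > 0 else 0.0
        log_mean = (base - truth.intercept) / truth.beta_log_mean
        beta1 = truth.beta_treatment
        if truth.interaction_predictor is not None:
            beta1 += truth.interaction_slope * (
                covs[truth.interaction_predictor] - truth.interaction_center
            )
        log_sd_pl = base + b_i
        log_sd_ve = base + b_i + beta1

        follow_up = rng.uniform(*truth.follow_up_range)
        n_pl = int(rng.integers(truth.n_range[0], truth.n_range[1] + 1))
        n_ve = int(rng.integers(truth.n_range[0], truth.n_range[1] + 1))

        truth_pl = _arm_truth_for_targets(
            log_mean, log_sd_pl, follow_up, truth.dropout_rate, n_pl
        )
        truth_ve = _arm_truth_for_targets(
            log_mean, log_sd_ve, follow_up, truth.dropout_rate, n_ve
        )
        ipd_pl = simulate_arm(truth_pl, ss[2 * i])
        ipd_ve = simulate_arm(truth_ve, ss[2 * i + 1])
        trial_id = f"trial_{i + 1:02d}"
        covs["trial_id"] = trial_id
        trials.append(
            SimulatedTrial(
                trial_id=trial_id,
                placebo=(truth_pl, ipd_pl),
                verum=(truth_ve, ipd_ve),
                covariates=covs,
            )
        )
    return trials


def default_risk_times(max_follow_up: float, step: float = 6.0) -> np.ndarray:
    """Every ``step`` months from 0, closing exactly at the follow-up cutoff."""
    ts = np.arange(0.0, max_follow_up, step)
    return np.append(ts, max_follow_up)


def render_km(ipd: IPD, risk_times) -> tuple[SurvivalCurve, RiskTable]:
    """Render records into the published-figure format the pipeline reads.

    Returns product-limit step coordinates (pre- and post-step value at every
    distinct event time, plus ``(0, 1)``) and the number still at risk
    (``time >= t``) at each requested risk time; total events are carried on
    the risk table.
    """
    if ipd.n == 0:
        raise InputError("empty IPD")
    risk_times = np.asarray(risk_times, dtype=float)
    if len(risk_times) < 2 or risk_times[0] != 0 or np.any(np.diff(risk_times) <= 0):
        raise InputError("risk_times must start at 0 and be strictly increasing")
    base = km_estimate(ipd)
    times = [0.0]
    surv = [1.0]
    for j in range(1, len(base)):
        times.extend([base.times[j], base.times[j]])
        surv.extend([base.survival[j - 1], base.survival[j]])
    if risk_times[-1] > times[-1]:  # published curves run flat to end of follow-up
        times.append(risk_times[-1])
        surv.append(surv[-1])
    curve = SurvivalCurve(np.array(times), np.array(surv))
    n_at_risk = np.array([(ipd.time >= t).sum() for t in risk_times], dtype=int)
    return curve, RiskTable(risk_times, n_at_risk, total_events=ipd.n_events)


def perturb_digitization(curve: SurvivalCurve, noise_sd: float, seed) -> SurvivalCurve:
    """Add digitization noise to the survival axis, then re-impose validity.

    Gaussian ``N(0, noise_sd^2)`` noise on every point except ``(0, 1)``,
    followed by pool-adjacent-violators (monotone non-increasing) and
    clipping to ``[0, 1]``.
    """
    if noise_sd < 0:
        raise InputError("noise_sd must be nonnegative")
    if noise_sd == 0:
        return curve
    rng = np.random.default_rng(seed)
    s = curve.survival.copy()
    keep = curve.times == 0.0
    noise = rng.normal(0.0, noise_sd, len(s))
    noise[keep] = 0.0
    s = np.clip(s + noise, 0.0, 1.0)
    s = isotonic_regression(s, increasing=False).x
    return SurvivalCurve(curve.times, np.clip(s, 0.0, 1.0))
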