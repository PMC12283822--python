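"""Censored Weibull fitting and the per-arm variability summary.

Each trial arm's reconstructed times to death are modelled as Weibull with
shape ``k`` and scale ``lam`` (months), survival ``S(t) = exp(-(t/lam)^k)``.
The censored log-likelihood is

    sum_events [ log k - k log lam + (k-1) log t - (t/lam)^k ]
  + sum_censored [ -(t/lam)^k ]

and is maximized over ``(log k, log lam)`` with analytic gradient and
Hessian (profile likelihood in ``log k`` for initialization, then damped
Newton polish).  The covariance of the log-parameters is the inverse
observed information at the optimum.

The variability outcome of an arm is the natural log of the standard
deviation of the *uncensored* Weibull death-time law,

    Mean = lam * Gamma(1 + 1/k)
    SD   = lam * sqrt(Gamma(1 + 2/k) - Gamma(1 + 1/k)^2),

with its sampling variance obtained by the delta method (note
``d logSD / d log lam = 1``).  Censoring enters only through the likelihood:
with follow-up far shorter than the fitted mean time to death these are
extrapolated-distribution moments, which is exactly what makes arms with
different follow-up comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, solve
from scipy.optimize import brentq, minimize_scalar
from scipy.special import digamma, gamma, gammaln, logsumexp

from .errors import FitError, InputError, ParameterError
from .reconstruct import IPD

__all__ = [
    "WeibullFit",
    "ArmVariability",
    "fit_weibull",
    "weibull_mean_sd",
    "weibull_moments",
    "log_sd",
    "log_mean",
    "var_log_sd",
    "bootstrap_var_log_sd",
    "arm_summary",
    "weibull_parameters_for_moments",
    "arms_to_frame",
    "frame_to_arms",
]

_LOGK_LO, _LOGK_HI = np.log(1e-2), np.log(1e3)
_GRAD_TOL = 1e-8


@dataclass(frozen=True)
class WeibullFit:
    """Maximum-likelihood Weibull fit of one arm."""

    shape: float
    scale: float
    loglik: float
    cov_log_params: np.ndarray  # 2x2, order (log shape, log scale)
    n: int
    n_events: int


@dataclass(frozen=True)
class ArmVariability:
    """One observation of the meta-regression: an arm's variability summary."""

    trial_id: str
    treatment: int  # 1 = verum, 0 = placebo
    log_sd: float
    log_mean: float
    var_log_sd: float
    n: int
    n_events: int

    def __post_init__(self):
        if self.treatment not in (0, 1):
            raise InputError("treatment must be 0 (placebo) or 1 (verum)")
        if not self.var_log_sd > 0:
            raise InputError("var_log_sd must be positive")


def _derivs(a: float, b: float, logt: np.ndarray, ev: np.ndarray):
    """Log-likelihood, gradient and Hessian in (a, b) = (log k, log lam)."""
    k = np.exp(a)
    u = logt - b
    z = np.exp(np.clip(k * u, -745.0, 700.0))
    d = int(ev.sum())
    ue = u[ev]
    ll = d * a + k * ue.sum() - logt[ev].sum() - z.sum()
    zu = z * u
    g_a = d + k * ue.sum() - k * zu.sum()
    g_b = k * (z.sum() - d)
    zu2 = zu * u
    h_aa = k * (ue.sum() - zu.sum() - k * zu2.sum())
    h_ab = k * (-d + z.sum() + k * zu.sum())
    h_bb = -(k**2) * z.sum()
    return ll, np.array([g_a, g_b]), np.array([[h_aa, h_ab], [h_ab, h_bb]])


def _profile_b(a: float, logt: np.ndarray, d: int) -> float:
    k = np.exp(a)
    return (logsumexp(k * logt) - np.log(d)) / k


def fit_weibull(ipd: IPD) -> WeibullFit:
    """Censored Weibull MLE; requires at least 2 events at 2 distinct times."""
    ev = ipd.event.astype(bool)
    d = int(ev.sum())
    if d < 2 or np.unique(ipd.time[ev]).size < 2:
        raise FitError(
            "insufficient events: need >= 2 events at >= 2 distinct times "
            f"(got {d} events)"
        )
    logt = np.log(ipd.time)

    def prof_nll(a):
        b = _profile_b(a, logt, d)
        return -_derivs(a, b, logt, ev)[0]

    res = minimize_scalar(
        prof_nll, bounds=(_LOGK_LO, _LOGK_HI), method="bounded",
        options={"xatol": 1e-11},
    )
    a = float(res.x)
    b = _profile_b(a, logt, d)
    if a < _LOGK_LO + 1e-6 or a > _LOGK_HI - 1e-6:
        raise FitError(f"shape estimate at search boundary (k={np.exp(a):.3g})")

    ll, g, H = _derivs(a, b, logt, ev)
    for _ in range(60):
        if np.linalg.norm(g) < _GRAD_TOL:
            break
        try:
            step = solve(H, g)
        except LinAlgError as exc:
            raise FitError("singular observed information during Newton polish") from exc
        scale = 1.0
        for _ in range(30):  # backtracking: Newton step must not decrease ll
            a2, b2 = a - scale * step[0], b - scale * step[1]
            ll2, g2, H2 = _derivs(a2, b2, logt, ev)
            if ll2 >= ll - 1e-12:
                break
            scale /= 2.0
        a, b, ll, g, H = a2, b2, ll2, g2, H2
    gnorm = float(np.linalg.norm(g))
    if gnorm > _GRAD_TOL:
        raise FitError(f"Weibull fit did not converge (|grad|={gnorm:.2e})")

    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular observed information at the optimum") from exc
    if np.any(np.linalg.eigvalsh(cov) <= 0):
        raise FitError("observed information is not positive definite")
    return WeibullFit(
        shape=float(np.exp(a)),
        scale=float(np.exp(b)),
        loglik=float(ll),
        cov_log_params=cov,
        n=ipd.n,
        n_events=d,
    )


def weibull_mean_sd(shape: float, scale: float) -> tuple[float, float]:
    """Closed-form mean and SD of the (uncensored) Weibull law."""
    if shape <= 0 or scale <= 0:
        raise ParameterError("shape and scale must be positive")
    g1 = gamma(1.0 + 1.0 / shape)
    # variance via gammaln for numerical headroom at small shape
    var_over_scale2 = np.expm1(gammaln(1.0 + 2.0 / shape) - 2.0 * gammaln(1.0 + 1.0 / shape))
    var_over_scale2 *= g1**2
    return float(scale * g1), float(scale * np.sqrt(max(var_over_scale2, 0.0)))


def weibull_moments(fit: WeibullFit) -> tuple[float, float]:
    return weibull_mean_sd(fit.shape, fit.scale)


def log_sd(fit: WeibullFit) -> float:
    return float(np.log(weibull_moments(fit)[1]))


def log_mean(fit: WeibullFit) -> float:
    return float(np.log(weibull_moments(fit)[0]))


def _dlogsd_dlogk(k: float) -> float:
    """d log SD / d log k for the Weibull SD (d log SD / d log lam is 1)."""
    g1 = gamma(1.0 + 1.0 / k)
    g2 = gamma(1.0 + 2.0 / k)
    v = g2 - g1**2
    num = g2 * digamma(1.0 + 2.0 / k) - g1**2 * digamma(1.0 + 1.0 / k)
    return float(-num / (k * v))


def var_log_sd(fit: WeibullFit) -> float:
    """Delta-method sampling variance of log SD from the log-parameter covariance."""
    grad = np.array([_dlogsd_dlogk(fit.shape), 1.0])
    v = float(grad @ fit.cov_log_params @ grad)
    if not v > 0:
        raise FitError("delta-method variance of log SD is not positive")
    return v


def bootstrap_var_log_sd(ipd: IPD, B: int = 500, seed: int = 0) -> float:
    """Nonparametric (case-resampling) bootstrap variance of log SD.

    Serves as an independent check on the delta method; errors out when more
    than 10% of the ``B`` refits fail.
    """
    if B < 100:
        raise InputError("B must be at least 100")
    rng = np.random.default_rng(seed)
    vals = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, ipd.n, ipd.n)
        try:
            fit = fit_weibull(IPD(ipd.time[idx], ipd.event[idx]))
            vals.append(log_sd(fit))
        except FitError:
            failures += 1
    if failures > 0.1 * B:
        raise FitError(f"{failures}/{B} bootstrap refits failed")
    return float(np.var(vals, ddof=1))


def arm_summary(trial_id: str, treatment: int, ipd: IPD) -> ArmVariability:
    """Fit one arm and assemble its meta-regression observation."""
    fit = fit_weibull(ipd)
    return ArmVariability(
        trial_id=str(trial_id),
        treatment=int(treatment),
        log_sd=log_sd(fit),
        log_mean=log_mean(fit),
        var_log_sd=var_log_sd(fit),
        n=fit.n,
        n_events=fit.n_events,
    )


def weibull_parameters_for_moments(mean: float, sd: float) -> tuple[float, float]:
    """Solve (shape, scale) so the Weibull law has the given mean and SD.

    The coefficient of variation determines the shape uniquely (CV(k) is
    strictly decreasing), then the scale follows from the mean.
    """
    if mean <= 0 or sd <= 0:
        raise ParameterError("mean and sd targets must be positive")
    target = np.log1p((sd / mean) ** 2)

    def f(k):
        return gammaln(1.0 + 2.0 / k) - 2.0 * gammaln(1.0 + 1.0 / k) - target

    lo, hi = 1e-2, 1e3
    if f(lo) < 0 or f(hi) > 0:
        raise ParameterError(
            f"coefficient of variation {sd / mean:.3g} outside solvable range"
        )
    k = brentq(f, lo, hi, xtol=1e-13, rtol=1e-14)
    lam = mean / gamma(1.0 + 1.0 / k)
    return float(k), float(lam)


# ---------------------------------------------------------------------------
# arm-summary CSV schema (mirrors the arm-level analysis dataset layout)

_ARM_COLUMNS = ["trial_id", "treatment", "log_sd", "log_mean", "var_log_sd", "n", "n_events"]


def arms_to_frame(arms: list[ArmVariability]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(a, c) for c in _ARM_COLUMNS} for a in arms])


def frame_to_arms(df: pd.DataFrame) -> list[ArmVariability]:
    return [
        ArmVariability(
            trial_id=str(r.trial_id),
            treatment=int(r.treatment),
            log_sd=float(r.log_sd),
            log_mean=float(r.log_mean),
            var_log_sd=float(r.var_log_sd),
            n=int(r.n),
            n_events=int(r.n_events),
        )
        for r in df.itertuples(index=False)
    ]
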