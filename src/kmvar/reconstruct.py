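"""Rebuild individual time-to-event records from published Kaplan-Meier curves.

Large trials rarely share individual participant data (IPD), but their reports
print Kaplan-Meier curves together with number-at-risk tables.  Digitizing a
curve yields step coordinates ``(time, survival)``; combining those with the
at-risk counts allows an essentially lossless reconstruction of one
``(time, status)`` record per participant — the iterative algorithm of
Guyot et al. (2012).

The module provides

* :func:`clean_curve` — repair digitization jitter (clipping, monotonicity via
  pool-adjacent-violators, duplicate collapsing),
* :func:`reconstruct_ipd` — the interval-by-interval reconstruction,
* :func:`km_estimate` — the product-limit estimator, used for round-trip
  verification of a reconstruction against the digitized input.

Times are measured in months throughout; survival probabilities live on
``[0, 1]`` (a percent axis is detected and divided by 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .errors import InputError, ReconstructionError

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "RiskTable",
    "IPD",
    "clean_curve",
    "reconstruct_ipd",
    "km_estimate",
]


def _vector(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class SurvivalCurve:
    """Step coordinates of one arm's (digitized) Kaplan-Meier curve."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", _vector(self.times, "times"))
        object.__setattr__(self, "survival", _vector(self.survival, "survival"))
        if self.times.shape != self.survival.shape:
            raise InputError("times and survival must have equal length")
        if np.any(self.times < 0):
            raise InputError("times must be nonnegative")

    def __len__(self) -> int:
        return len(self.times)

    def at(self, t) -> np.ndarray:
        """Right-continuous step interpolation S(t)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.survival[np.clip(idx, 0, len(self) - 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survival})


@dataclass(frozen=True)
class RiskTable:
    """Published number-at-risk table for one arm."""

    times: np.ndarray
    n_at_risk: np.ndarray
    total_events: int | None = None

    def __post_init__(self):
        times = _vector(self.times, "risk times")
        counts = np.atleast_1d(np.asarray(self.n_at_risk))
        if times.shape != counts.shape:
            raise InputError("risk times and counts must have equal length")
        if len(times) < 2:
            raise InputError("risk table needs at least two time points")
        if times[0] != 0:
            raise InputError("risk table must start at time 0")
        if np.any(np.diff(times) <= 0):
            raise InputError("risk times must be strictly increasing")
        counts = counts.astype(int)
        if np.any(counts < 0):
            raise InputError("n_at_risk must be nonnegative")
        if np.any(np.diff(counts) > 0):
            raise InputError("n_at_risk must be non-increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "n_at_risk", counts)
        if self.total_events is not None and int(self.total_events) < 0:
            raise InputError("total_events must be nonnegative")


@dataclass(frozen=True)
class IPD:
    """Individual (time, status) records for one arm; status 1 = death."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        time = _vector(self.time, "time")
        event = np.atleast_1d(np.asarray(self.event)).astype(int)
        if time.shape != event.shape:
            raise InputError("time and event must have equal length")
        if np.any(time <= 0):
            raise InputError("all times must be strictly positive")
        if not np.isin(event, (0, 1)).all():
            raise InputError("event indicator must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "status": self.event})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IPD":
        return cls(df["time_months"].to_numpy(float), df["status"].to_numpy(int))


def clean_curve(raw: SurvivalCurve) -> SurvivalCurve:
    """Repair a digitized curve so it is a valid survival step function.

    Steps: percent axis detection (max > 1.5 ⇒ divide by 100), clipping to
    [0, 1], stable sort by time, collapse of duplicate times keeping the
    minimum (post-step) survival, prepending ``(0, 1)`` when absent, and
    monotone non-increase enforced by pool-adjacent-violators.  Idempotent.
    """
    if len(raw) < 2:
        raise InputError("need at least two digitized points")
    t = raw.times.copy()
    s = raw.survival.copy()
    if np.max(s) > 1.5:  # percent axis
        s = s / 100.0
    s = np.clip(s, 0.0, 1.0)
    order = np.argsort(t, kind="stable")
    t, s = t[order], s[order]
    # duplicate times: keep the post-step (minimum) value
    df = pd.DataFrame({"t": t, "s": s}).groupby("t", sort=True)["s"].min()
    t = df.index.to_numpy(float)
    s = df.to_numpy(float)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    else:
        s[0] = 1.0
    s = isotonic_regression(s, increasing=False).x
    s = np.clip(s, 0.0, 1.0)
    return SurvivalCurve(t, s)


def km_estimate(ipd: IPD) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimator of a set of records.

    Returns ``(0, 1)`` followed by the post-step survival value at every
    distinct event time, computed as an exact running product.
    """
    if ipd.n == 0:
        raise InputError("empty IPD")
    order = np.argsort(ipd.time, kind="stable")
    t = ipd.time[order]
    e = ipd.event[order].astype(bool)
    ev_times, d = np.unique(t[e], return_counts=True)
    if len(ev_times) == 0:
        return SurvivalCurve([0.0], [1.0])
    at_risk = ipd.n - np.searchsorted(t, ev_times, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    return SurvivalCurve(
        np.concatenate([[0.0], ev_times]), np.concatenate([[1.0], surv])
    )


def _interval_pass(t, S, k_start, k_end, t_start, t_stop, n0, km0, nc):
    """One deterministic pass over a risk-table interval for a censor guess.

    Censor times are spread uniformly over ``(t_start, t_stop)``; event counts
    at each digitized step follow from the KM ratio against the running
    reconstructed estimate, rounded half-up with a running remainder so that
    interval totals are preserved.
    """
    if nc > 0:
        span = t_stop - t_start
        c = t_start + span * (np.arange(1, nc + 1) / (nc + 1.0))
    else:
        c = np.empty(0)
    clicks = t[k_start:k_end]
    if len(clicks):
        gap = np.searchsorted(clicks, c, side="right") - 1
        cen_before = int(np.sum(gap < 0))
        gap_counts = np.bincount(gap[gap >= 0], minlength=len(clicks))
    else:
        cen_before = nc
        gap_counts = np.empty(0, dtype=int)
    d = np.zeros(len(clicks), dtype=int)
    n = n0 - cen_before
    km = km0
    carry = 0.0
    ev = 0
    for j in range(len(clicks)):
        k = k_start + j
        if n > 0 and km > 0:
            desired = n * (1.0 - S[k] / km)
            x = desired + carry
            dk = int(np.floor(x + 0.5))
            dk = min(max(dk, 0), n)
            carry = x - dk
        else:
            dk = 0
        if dk > 0:
            km *= 1.0 - dk / n
        d[j] = dk
        ev += dk
        n -= dk + int(gap_counts[j])
    return SimpleNamespace(d=d, censor_times=c, n_end=n, km_end=km, n_events=ev)


def _match_boundary(t, S, k_start, k_end, t_start, t_stop, n_hat, km, target, i, Tr):
    """Iterate the censor count until the at-risk count at the boundary matches."""
    s_a = S[k_start] if k_start < len(S) else S[-1]
    s_b = S[min(k_end, len(S) - 1)]
    guess = (int(round(n_hat * s_b / s_a)) - target) if s_a > 0 else 0
    nc = max(int(guess), 0)
    tried: set[int] = set()
    best = None  # (|diff|, nc, state)
    for _ in range(n_hat + 2):
        state = _interval_pass(t, S, k_start, k_end, t_start, t_stop, n_hat, km, nc)
        diff = state.n_end - target
        tried.add(nc)
        cand = (abs(diff), nc, state)
        if best is None or cand[:2] < best[:2]:
            best = cand
        if diff == 0:
            break
        nxt = max(nc + diff, 0)
        if nxt in tried:
            break
        nc = nxt
    if best[0] != 0:
        # fixed-point iteration can oscillate when a censoring flips a rounded
        # event count; scan the neighborhood of the best guess before failing
        for nc in range(max(best[1] - 30, 0), best[1] + 31):
            if nc in tried:
                continue
            state = _interval_pass(t, S, k_start, k_end, t_start, t_stop, n_hat, km, nc)
            diff = state.n_end - target
            cand = (abs(diff), nc, state)
            if cand[:2] < best[:2]:
                best = cand
            if diff == 0:
                break
    if best[0] != 0:
        # rounding can leave a one-off parity trap (adding a censoring flips
        # an event); a small residual is tolerated and propagated, as in the
        # original algorithm — only gross mismatches indicate bad inputs
        if best[0] > max(2, 0.01 * n_hat):
            raise ReconstructionError(
                f"interval {i} ending at t={Tr[i + 1]:g}: cannot match published "
                f"number at risk {target} (off by {best[0]})"
            )
        logger.debug(
            "interval %d: at-risk count matched within %d of %d", i, best[0], target
        )
    return best[1], best[2]


def _run_tail(t, S, k_start, t_start, n_hat, km, events_missing):
    """Process clicks after the last risk-table time, matching remaining events.

    ``events_missing`` is the number of events still needed to reach the
    supplied total (None when no total was given).
    """
    K = len(t)
    t_stop = t[-1]
    nc = 0
    tried: set[int] = set()
    best = None
    for _ in range(n_hat + 2):
        state = _interval_pass(t, S, k_start, K, t_start, t_stop, n_hat, km, nc)
        diff = 0 if events_missing is None else state.n_events - events_missing
        tried.add(nc)
        cand = (abs(diff), nc, state)
        if best is None or cand[:2] < best[:2]:
            best = cand
        if diff == 0:
            break
        nxt = max(nc + diff, 0)
        if nxt in tried:
            break
        nc = nxt
    return best[0], best[2]


def reconstruct_ipd(
    curve: SurvivalCurve, risk: RiskTable, total_events: int | None = None
) -> IPD:
    """Reconstruct individual records from a digitized curve and risk table.

    For each interval between consecutive risk-table times the number of
    censorings is guessed, censoring times are placed uniformly within the
    interval, event counts at each digitized step are derived from the KM
    ratios and the running at-risk count, and the guess is iterated until the
    reconstructed number at risk at the next risk-table time matches the
    published value (ties broken toward fewer censorings).  When
    ``total_events`` is supplied, the censoring allocation of the final
    stretch (the last inter-risk interval together with anything after the
    last risk-table time) is adjusted so the reconstructed event count equals
    it; within the boundary-satisfying allocations each additional censoring
    trades exactly one event, which is what makes the adjustment possible.
    Participants still at risk after the last digitized time are censored
    there.

    The reconstructed cohort size always equals ``risk.n_at_risk[0]``.
    """
    curve = clean_curve(curve)
    t, S = curve.times, curve.survival
    if total_events is None:
        total_events = risk.total_events
    Tr = risk.times
    R = risk.n_at_risk
    if t[-1] < Tr[-1]:
        raise InputError("curve does not span the risk-table time range")
    if R[0] < 1:
        raise InputError("initial number at risk must be at least 1")
    K = len(t)
    M = len(Tr)
    lower = np.searchsorted(t, Tr, side="left")

    events = np.zeros(K, dtype=int)
    censor_times: list[np.ndarray] = []
    n_hat = int(R[0])
    km = 1.0
    tot_ev = 0

    def commit(k_start, k_end, state):
        nonlocal n_hat, km, tot_ev
        events[k_start:k_end] = state.d
        if len(state.censor_times):
            censor_times.append(state.censor_times)
        n_hat = state.n_end
        km = state.km_end
        tot_ev += state.n_events

    # interior intervals: match the published at-risk count at each boundary
    for i in range(M - 2):
        k_start, k_end = int(lower[i]), int(lower[i + 1])
        t_stop = t[min(k_end, K - 1)]
        _, state = _match_boundary(
            t, S, k_start, k_end, Tr[i], t_stop, n_hat, km, int(R[i + 1]), i, Tr
        )
        commit(k_start, k_end, state)

    # final stretch: last boundary interval plus the tail after the last risk
    # time, jointly constrained by the last at-risk count and (optionally) the
    # total number of events
    i = M - 2
    k_start, k_end = int(lower[i]), int(lower[i + 1])
    t_stop = t[min(k_end, K - 1)]
    nc_opt, state_opt = _match_boundary(
        t, S, k_start, k_end, Tr[i], t_stop, n_hat, km, int(R[i + 1]), i, Tr
    )

    def with_tail(state):
        missing = None if total_events is None else total_events - tot_ev - state.n_events
        return _run_tail(t, S, k_end, Tr[i + 1], state.n_end, state.km_end, missing)

    tail_diff, tail_state = with_tail(state_opt)
    if tail_diff != 0:
        # walk the contiguous set of boundary-satisfying censor counts; each
        # step exchanges one censoring for one event in the last interval
        best = (tail_diff, nc_opt, state_opt, tail_state)
        for direction in (1, -1):
            nc = nc_opt
            for _ in range(2 * abs(tail_diff) + 25):
                nc += direction
                if nc < 0:
                    break
                st = _interval_pass(t, S, k_start, k_end, Tr[i], t_stop, n_hat, km, nc)
                if st.n_end != R[i + 1]:
                    break
                td, ts = with_tail(st)
                if abs(td) < abs(best[0]):
                    best = (td, nc, st, ts)
                if td == 0:
                    break
            if best[0] == 0:
                break
        tail_diff, _, state_opt, tail_state = best
        if tail_diff != 0:
            logger.warning(
                "total events constraint met only approximately (off by %d)", tail_diff
            )
    commit(k_start, k_end, state_opt)
    commit(k_end, K, tail_state)

    ev_rep = np.repeat(t, events)
    cens = np.concatenate(censor_times) if censor_times else np.empty(0)
    tail = np.full(n_hat, t[-1])  # still at risk after the last digitized time
    time = np.concatenate([ev_rep, cens, tail])
    status = np.concatenate(
        [np.ones(len(ev_rep), int), np.zeros(len(cens) + len(tail), int)]
    )
    if len(time) != R[0]:  # conservation of the cohort
        raise ReconstructionError(
            f"reconstructed {len(time)} records for an initial at-risk count of {R[0]}"
        )
    return IPD(time, status)


# ---------------------------------------------------------------------------
# CSV schemas shared with the simulator and pipeline


def curves_to_frame(curves: dict[tuple[str, str], SurvivalCurve]) -> pd.DataFrame:
    rows = []
    for (trial_id, arm), curve in curves.items():
        df = curve.to_frame()
        df.insert(0, "arm", arm)
        df.insert(0, "trial_id", trial_id)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def frame_to_curves(df: pd.DataFrame) -> dict[tuple[str, str], SurvivalCurve]:
    out = {}
    for (trial_id, arm), grp in df.groupby(["trial_id", "arm"], sort=False):
        out[(str(trial_id), str(arm))] = SurvivalCurve(
            grp["time_months"].to_numpy(float), grp["survival"].to_numpy(float)
        )
    return out


def risk_tables_to_frame(tables: dict[tuple[str, str], RiskTable]) -> pd.DataFrame:
    rows = []
    for (trial_id, arm), rt in tables.items():
        df = pd.DataFrame(
            {
                "trial_id": trial_id,
                "arm": arm,
                "time_months": rt.times,
                "n_at_risk": rt.n_at_risk,
                "total_events": rt.total_events if rt.total_events is not None else -1,
            }
        )
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def frame_to_risk_tables(df: pd.DataFrame) -> dict[tuple[str, str], RiskTable]:
    out = {}
    for (trial_id, arm), grp in df.groupby(["trial_id", "arm"], sort=False):
        te = None
        if "total_events" in grp.columns:
            te_val = int(grp["total_events"].iloc[0])
            te = te_val if te_val >= 0 else None
        out[(str(trial_id), str(arm))] = RiskTable(
            grp["time_months"].to_numpy(float),
            grp["n_at_risk"].to_numpy(int),
            total_events=te,
        )
    return out
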