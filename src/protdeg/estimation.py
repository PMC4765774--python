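"""Balanced-growth estimation of apparent degradation rates.

During balanced exponential growth the per-cell protein level P = activity/OD
is quasi-stationary, so the zero-order mass balance ``dP/dt + μ·P = α − β``
can be read directly from finite-difference slopes of consecutive samples:

1. per-cell signal P_j = activity_j / OD_j,
2. per-interval growth rate μ_i from log-OD slopes (dilution-corrected),
3. per-interval net rate  (α − β)_i = dP/dt_i + μ_i·P̄_i,
4. mean net rate over a short balanced window (3–5 time points),
5. apparent degradation β = net rate of a no-degradation control (e.g. a
   ΔclpP strain) minus the net rate of the test condition.

All quantities stay in measurement units (signal·OD⁻¹ and rates thereof)
until converted with :mod:`protdeg.units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GrowthTimeCourse",
    "IntervalEstimate",
    "ApparentDegradationRate",
    "InsufficientDataError",
    "per_cell_signal",
    "cumulative_od",
    "compute_interval_estimates",
    "estimate_net_rate",
    "estimate_beta",
    "compare_conditions",
    "zero_order_validity_check",
]


class InsufficientDataError(ValueError):
    """Too few intervals to estimate a balanced-growth rate."""


@dataclass(frozen=True)
class GrowthTimeCourse:
    """One biological replicate's measured series with condition metadata.

    ``dilution_factor`` is a per-sample multiplicative factor (1 when no
    dilution occurred before that sample); it corrects OD to cumulative
    biomass for growth-rate computation while leaving the per-cell signal
    untouched.
    """

    condition: str
    replicate: str
    times: np.ndarray
    od: np.ndarray
    activity: np.ndarray
    dilution_factor: Optional[np.ndarray] = None
    units: str = "RFU_per_OD"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        act = np.asarray(self.activity, dtype=float)
        if self.dilution_factor is None:
            dil = np.ones_like(t)
        else:
            dil = np.asarray(self.dilution_factor, dtype=float)
        for name, arr in (("od", od), ("activity", act), ("dilution_factor", dil)):
            if arr.shape != t.shape:
                raise ValueError(f"{name} must match times in length")
        if t.size < 2:
            raise ValueError("a time course needs at least 2 time points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od <= 0):
            raise ValueError("OD readings must be strictly positive")
        if np.any(dil < 1):
            raise ValueError("dilution_factor must be >= 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)
        object.__setattr__(self, "activity", act)
        object.__setattr__(self, "dilution_factor", dil)


@dataclass(frozen=True)
class IntervalEstimate:
    """Finite-difference rates over one sampling interval.

    ``net_rate`` satisfies ``net_rate = dpdt + mu * p_avg`` by construction;
    under the zero-order model it estimates α − β on that interval.
    """

    t_mid: float
    mu: float
    dpdt: float
    p_avg: float
    net_rate: float


@dataclass(frozen=True)
class ApparentDegradationRate:
    """A condition's apparent zero-order degradation rate β with dispersion."""

    beta: float
    sem: float
    n: int
    condition: str
    control: str
    zero_order_warning: bool = False

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be nonnegative")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def per_cell_signal(tc: GrowthTimeCourse) -> np.ndarray:
    """Per-cell protein proxy P_j = activity_j / OD_j (signal·OD⁻¹).

    Dilution leaves P unchanged: it is an intensive, per-cell quantity.
    """
    return tc.activity / tc.od


def cumulative_od(tc: GrowthTimeCourse) -> np.ndarray:
    """OD corrected for dilution events: OD_cum_j = OD_j · Π dilution_factor_{≤j}.

    This is the biomass the culture would have reached without dilution and
    is what log-slopes are taken on to compute μ.
    """
    return tc.od * np.cumprod(tc.dilution_factor)


def compute_interval_estimates(tc: GrowthTimeCourse) -> list[IntervalEstimate]:
    """Finite-difference rates for each consecutive pair of samples.

    Per interval (j, j+1): μ_i from log cumulative-OD slope, dP/dt from the
    per-cell signal slope, P̄ the arithmetic mean of the endpoints, and
    ``net_rate = dP/dt + μ·P̄``.
    """
    t = tc.times
    p = per_cell_signal(tc)
    od_cum = cumulative_od(tc)
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ValueError("zero-length interval in time course")
    mu = np.diff(np.log(od_cum)) / dt
    dpdt = np.diff(p) / dt
    p_avg = (p[:-1] + p[1:]) / 2.0
    net = dpdt + mu * p_avg
    t_mid = (t[:-1] + t[1:]) / 2.0
    return [
        IntervalEstimate(t_mid=float(tm), mu=float(m), dpdt=float(d),
                         p_avg=float(pa), net_rate=float(nr))
        for tm, m, d, pa, nr in zip(t_mid, mu, dpdt, p_avg, net)
    ]


def _select_window(mus: np.ndarray, max_intervals: int, mu_tol: float) -> slice:
    """Pick the balanced-growth window of intervals.

    If no more intervals than the cap exist, use them all. Otherwise take
    the earliest contiguous run of ``max_intervals`` intervals whose μ
    values agree to within ``mu_tol`` relative spread; if none qualifies,
    fall back to the first ``max_intervals`` intervals.
    """
    n = mus.size
    if n <= max_intervals:
        return slice(0, n)
    for start in range(n - max_intervals + 1):
        win = mus[start:start + max_intervals]
        center = np.mean(np.abs(win))
        if center == 0:
            if np.ptp(win) == 0:
                return slice(start, start + max_intervals)
            continue
        if np.ptp(win) / center < mu_tol:
            return slice(start, start + max_intervals)
    return slice(0, max_intervals)


def estimate_net_rate(
    tc: GrowthTimeCourse,
    max_intervals: int = 4,
    mu_tol: float = 0.15,
) -> float:
    """Mean net rate α − β over the balanced-growth window.

    At most ``max_intervals`` consecutive intervals (default 4, i.e. five
    time points) are averaged; at least three intervals are required.

    Raises
    ------
    InsufficientDataError
        If fewer than three intervals are available.
    """
    intervals = compute_interval_estimates(tc)
    if len(intervals) < 3:
        raise InsufficientDataError(
            f"condition {tc.condition!r} replicate {tc.replicate!r}: "
            f"{len(intervals)} interval(s) available, need >= 3"
        )
    mus = np.array([iv.mu for iv in intervals])
    window = _select_window(mus, max_intervals, mu_tol)
    return float(np.mean([iv.net_rate for iv in intervals[window]]))


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def estimate_beta(
    condition_reps: Sequence[float],
    control_reps: Sequence[float],
    condition: str = "condition",
    control: str = "control",
    sem_mode: str = "propagated",
) -> ApparentDegradationRate:
    """Apparent degradation rate by control subtraction.

    ``beta = mean(control net rates) − mean(condition net rates)``. The
    control shares the synthesis rate α but lacks degradation (β=0), so the
    difference of mean net rates isolates β. The s.e.m. is propagated in
    quadrature across the two independent groups (``sem_mode="propagated"``,
    default) or taken from the test condition alone
    (``sem_mode="condition_only"``). Negative estimates are reported as-is.
    """
    cond = np.asarray(condition_reps, dtype=float)
    ctrl = np.asarray(control_reps, dtype=float)
    if cond.size == 0 or ctrl.size == 0:
        raise ValueError("both replicate groups must be nonempty")
    beta = float(np.mean(ctrl) - np.mean(cond))
    if sem_mode == "propagated":
        sem = float(np.hypot(_sem(cond), _sem(ctrl)))
    elif sem_mode == "condition_only":
        sem = _sem(cond)
    else:
        raise ValueError(f"unknown sem_mode {sem_mode!r}")
    return ApparentDegradationRate(
        beta=beta, sem=sem, n=int(cond.size), condition=condition, control=control
    )


def compare_conditions(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value between two groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2 for a two-sample test")
    if np.var(a) == 0 and np.var(b) == 0:
        # Degenerate: the t statistic is 0/0; identical constants are
        # indistinguishable, distinct constants are trivially separated.
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def zero_order_validity_check(p_values, km: float) -> bool:
    """Flag (not fail) when the zero-order assumption P ≫ Km is doubtful.

    Returns True when ``min(P) < 10·Km`` (strict), signalling that the
    apparent β may be biased low by first-order kinetics — expected when
    abundance falls toward Km, e.g. after synthesis repression.
    ``p_values`` and ``km`` must share units (convert first).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return False
    return bool(np.min(p) < 10.0 * km)
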