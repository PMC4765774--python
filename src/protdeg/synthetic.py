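"""Synthetic time-course generator.

Emulates shake-flask balanced-growth and induction experiments: exponential
OD600 growth with dilution events at an OD threshold, a per-cell protein
level following the degradation ODE, and multiplicative lognormal
measurement noise on both OD and activity. Every stage of the estimation
pipeline can thus be exercised end-to-end without laboratory data, with
known ground-truth rates.

All randomness flows from a single ``numpy`` Generator seeded by
``ExperimentDesign.seed``; identical designs produce bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .estimation import GrowthTimeCourse
from .model import (
    DegradationModelParams,
    steady_state,
    zero_order_solution,
    _degradation_rate,
)

__all__ = [
    "Condition",
    "ExperimentDesign",
    "generate_balanced_growth",
    "generate_induction_experiment",
]


@dataclass(frozen=True)
class Condition:
    """A genetic condition to simulate: label, model parameters, control flag."""

    label: str
    params: DegradationModelParams
    is_control: bool = False


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a simulated culture experiment.

    Defaults mirror a typical shake-flask run: hourly sampling over four
    hours of exponential growth at μ ≈ 1 h⁻¹ from OD 0.05, dilution into
    fresh medium whenever OD exceeds 1, six biological replicates, and 5 %
    multiplicative measurement noise (CV) applied independently to OD and
    activity readings.
    """

    conditions: tuple[Condition, ...] = ()
    replicates: int = 6
    t_start: float = 0.0
    t_end: float = 4.0
    sampling_interval: float = 1.0
    noise_cv: float = 0.05
    od0: float = 0.05
    dilution_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.od0 <= 0 or self.dilution_threshold <= 0:
            raise ValueError("od0 and dilution_threshold must be positive")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def sample_times(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.sampling_interval))
        return self.t_start + self.sampling_interval * np.arange(n + 1)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the requested CV."""
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _od_with_dilutions(
    od_true: np.ndarray, od0: float, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split undiluted biomass into measured OD and per-sample dilution factors.

    Whenever the culture OD would exceed ``threshold`` it is diluted back to
    ``od0`` into fresh medium; the factor is recorded at that sample so the
    cumulative biomass (and hence μ) can be reconstructed exactly.
    """
    n = od_true.size
    od = np.empty(n)
    dil = np.ones(n)
    cum = 1.0
    for j in range(n):
        current = od_true[j] / cum
        if current > threshold:
            factor = current / od0
            cum *= factor
            dil[j] = factor
            current = od_true[j] / cum
        od[j] = current
    return od, dil


def _make_timecourse(
    label: str,
    rep: int,
    times: np.ndarray,
    p_true: np.ndarray,
    od_true: np.ndarray,
    design: ExperimentDesign,
    rng: np.random.Generator,
) -> GrowthTimeCourse:
    od_real, dil = _od_with_dilutions(od_true, design.od0, design.dilution_threshold)
    eps_act = _lognormal_factors(rng, design.noise_cv, times.size)
    eps_od = _lognormal_factors(rng, design.noise_cv, times.size)
    return GrowthTimeCourse(
        condition=label,
        replicate=f"r{rep + 1}",
        times=times,
        od=od_real * eps_od,
        activity=p_true * od_real * eps_act,
        dilution_factor=dil,
        units="RFU_per_OD",
    )


def generate_balanced_growth(
    design: ExperimentDesign, km_aware: bool = False
) -> list[GrowthTimeCourse]:
    """Simulate balanced-growth replicates for every condition in the design.

    Each replicate starts at the model's steady state — the defining feature
    of balanced growth is a stationary per-cell protein level — so the
    ground-truth net rate is exactly α − β at every interval. In the default
    zero-order mode β = vmax and P(t) follows the closed-form linear
    solution; with ``km_aware=True`` the full Michaelis–Menten steady state
    is used instead.
    """
    rng = np.random.default_rng(design.seed)
    times = design.sample_times()
    t_rel = times - design.t_start
    out: list[GrowthTimeCourse] = []
    for cond in design.conditions:
        p = cond.params
        if km_aware:
            p_ss = steady_state(p)
        else:
            if p.mu <= 0:
                raise ValueError("balanced growth requires mu > 0")
            p_ss = max((p.alpha - p.vmax) / p.mu, 0.0)
        # Balanced growth: per-cell level stationary at the steady state.
        p_true = np.full_like(t_rel, p_ss)
        od_true = design.od0 * np.exp(p.mu * t_rel)
        for rep in range(design.replicates):
            out.append(_make_timecourse(cond.label, rep, times, p_true,
                                        od_true, design, rng))
    return out


def _induction_abundance(
    pre: DegradationModelParams,
    post: DegradationModelParams,
    t_induction: float,
    leak_fraction: float,
    clpp_delay: float,
    times: np.ndarray,
) -> np.ndarray:
    """Ground-truth per-cell abundance across an induction switch.

    Before ``t_induction`` the culture sits at the pre-condition steady
    state. At induction the synthesis rate drops to ``leak_fraction·α`` and
    degradation capacity ramps in with a first-order activation
    ``Vmax·(1 − e^(−Δt/clpp_delay))`` (instantaneous when the delay is 0),
    emulating the time needed to accumulate active protease.
    """
    p_ind = steady_state(pre)
    alpha_eff = leak_fraction * pre.alpha
    out = np.empty(times.size)
    pre_mask = times < t_induction
    out[pre_mask] = p_ind
    post_t = times[~pre_mask] - t_induction
    if post_t.size == 0:
        return out
    if clpp_delay == 0 and post.km == 0:
        # Exact zero-order closed form (valid while P > 0).
        vals = zero_order_solution(alpha_eff, post.vmax, post.mu, p_ind, post_t)
        out[~pre_mask] = np.clip(vals, 0.0, None)
        return out

    def rhs(t, y):
        p = max(y[0], 0.0)
        ramp = 1.0 if clpp_delay == 0 else -np.expm1(-t / clpp_delay)
        return [alpha_eff - post.mu * p - ramp * _degradation_rate(p, post.vmax, post.km)]

    t_span = (0.0, float(post_t[-1])) if post_t[-1] > 0 else (0.0, 1e-9)
    t_eval = post_t if post_t[-1] > 0 else None
    sol = solve_ivp(rhs, t_span, [p_ind], method="LSODA",
                    t_eval=t_eval, rtol=1e-8, atol=1e-6)
    if not sol.success:
        raise RuntimeError(f"induction integration failed: {sol.message}")
    vals = sol.y[0] if t_eval is not None else np.full(post_t.size, p_ind)
    out[~pre_mask] = np.clip(vals, 0.0, None)
    return out


def generate_induction_experiment(
    pre: DegradationModelParams,
    post: DegradationModelParams,
    t_induction: float,
    leak_fraction: float,
    clpp_delay: float,
    design: ExperimentDesign,
    label: str = "induced",
    od_lag: float = 0.0,
) -> list[GrowthTimeCourse]:
    """Simulate a media-swap induction experiment for one condition arm.

    The culture grows at ``pre.mu`` until ``t_induction`` with the target
    protein at its pre-induction steady state, is resuspended in fresh
    medium (OD reset to ``design.od0``), then grows at ``post.mu`` after an
    optional resuspension lag of ``od_lag`` hours during which OD is flat.
    Pair a degradation arm (``post.vmax > 0``) with a repression-only arm
    (``post.vmax = 0``) to feed :func:`protdeg.knockdown.estimate_induction_beta`.
    """
    rng = np.random.default_rng(design.seed)
    times = design.sample_times()
    p_true = _induction_abundance(pre, post, t_induction, leak_fraction,
                                  clpp_delay, times)
    od_true = np.empty(times.size)
    for j, t in enumerate(times):
        if t < t_induction:
            od_true[j] = design.od0 * np.exp(pre.mu * (t - design.t_start))
        else:
            dt = max(t - t_induction - od_lag, 0.0)
            od_true[j] = design.od0 * np.exp(post.mu * dt)
    out = []
    for rep in range(design.replicates):
        out.append(_make_timecourse(label, rep, times, p_true, od_true,
                                    design, rng))
    return out
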