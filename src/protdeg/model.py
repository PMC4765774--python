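"""Kinetic model of per-cell protein abundance in exponentially growing bacteria.

The model balances three processes acting on a per-cell protein count P
(proteins·cell⁻¹):

    dP/dt = α − μ·P − Vmax·P / (Km + P)

where α is the synthesis rate (proteins·cell⁻¹·h⁻¹), μ·P is dilution by
growth at specific growth rate μ (h⁻¹), and the last term is
Michaelis–Menten proteolysis with maximal rate Vmax and half-saturation
abundance Km (proteins·cell⁻¹).

When P ≫ Km the degradation term saturates and the equation reduces to the
zero-order form

    dP/dt + μ·P = α − β,   β ≈ Vmax,

which has the closed-form solution implemented in
:func:`zero_order_solution` and underlies the balanced-growth rate
estimation in :mod:`protdeg.estimation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DegradationModelParams",
    "Trajectory",
    "UnboundedGrowthError",
    "ode_rhs",
    "steady_state",
    "zero_order_solution",
    "simulate_trajectory",
]


class UnboundedGrowthError(ValueError):
    """No nonnegative equilibrium exists (synthesis outruns all sinks)."""


@dataclass(frozen=True)
class DegradationModelParams:
    """Rate constants and initial condition of the degradation ODE.

    Parameters
    ----------
    alpha : float
        Synthesis rate, proteins·cell⁻¹·h⁻¹.
    mu : float
        Specific growth (dilution) rate, h⁻¹.
    vmax : float
        Maximal degradation rate, proteins·cell⁻¹·h⁻¹. In the zero-order
        regime this equals the apparent degradation rate β.
    km : float
        Half-saturation abundance, proteins·cell⁻¹. ``km=0`` with
        ``vmax>0`` is interpreted as the strict zero-order limit
        (degradation = vmax for any P > 0), not an error.
    p0 : float
        Initial abundance, proteins·cell⁻¹.
    """

    alpha: float
    mu: float
    vmax: float = 0.0
    km: float = 0.0
    p0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "mu", "vmax", "p0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.km < 0:
            raise ValueError(f"km must be nonnegative, got {self.km}")


@dataclass(frozen=True)
class Trajectory:
    """A time series of per-cell abundance.

    ``units`` flags whether abundances are molecule counts
    (``"proteins_per_cell"``) or raw measurement units (``"RFU_per_OD"``).
    """

    times: np.ndarray
    abundances: np.ndarray
    units: str = "proteins_per_cell"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "abundances", p)
        if t.shape != p.shape:
            raise ValueError("times and abundances must have the same length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("abundances must be nonnegative")


def _degradation_rate(p: float, vmax: float, km: float) -> float:
    # km=0 is the strict zero-order limit: full vmax whenever protein remains.
    if km > 0:
        return vmax * p / (km + p)
    return vmax if p > 0 else 0.0


def ode_rhs(p: float, params: DegradationModelParams) -> float:
    """Instantaneous rate of change of per-cell abundance, dP/dt.

    Returns ``alpha − mu·p − vmax·p/(km + p)`` in proteins·cell⁻¹·h⁻¹.

    Raises
    ------
    ValueError
        If ``p`` is negative (abundance is a count).
    """
    if p < 0:
        raise ValueError(f"abundance must be nonnegative, got {p}")
    return params.alpha - params.mu * p - _degradation_rate(p, params.vmax, params.km)


def steady_state(params: DegradationModelParams) -> float:
    """The unique nonnegative root of the rate law.

    For ``mu > 0`` this is the nonnegative root of
    ``mu·P² + (mu·km + vmax − alpha)·P − alpha·km = 0``; for ``mu = 0`` a
    steady state exists only if Michaelis–Menten degradation can absorb
    the synthesis flux (``vmax > alpha``).

    Raises
    ------
    UnboundedGrowthError
        If no nonnegative equilibrium exists.
    ValueError
        If both ``mu`` and ``vmax`` are zero (with synthesis the abundance
        grows linearly forever; without, any p0 is an equilibrium).
    """
    a, mu, vmax, km = params.alpha, params.mu, params.vmax, params.km
    if mu == 0 and vmax == 0:
        raise ValueError("steady_state requires mu > 0 or vmax > 0")
    if a == 0:
        return 0.0
    if mu == 0:
        # alpha = vmax*P/(km+P): solvable only when the protease can saturate
        # above the synthesis flux.
        if vmax > a:
            return a * km / (vmax - a)
        raise UnboundedGrowthError(
            "synthesis exceeds the saturable degradation capacity with mu = 0"
        )
    if km == 0:
        return max((a - vmax) / mu, 0.0)
    b = mu * km + vmax - a
    # Discriminant b² + 4·mu·alpha·km > 0, so exactly one nonnegative root.
    return (-b + np.sqrt(b * b + 4.0 * mu * a * km)) / (2.0 * mu)


def zero_order_solution(alpha, beta, mu, p0, t):
    """Closed-form solution of ``dP/dt = α − β − μ·P``.

    ``P(t) = (α−β)/μ + (p0 − (α−β)/μ)·e^(−μt)``; for ``mu = 0`` the linear
    limit ``p0 + (α−β)·t``. Accepts scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    net = alpha - beta
    if mu == 0:
        out = p0 + net * t
    else:
        c = net / mu
        out = c + (p0 - c) * np.exp(-mu * t)
    return out if out.ndim else float(out)


def simulate_trajectory(
    params: DegradationModelParams,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> Trajectory:
    """Numerically integrate the full Michaelis–Menten ODE from ``params.p0``.

    Uses an adaptive-step integrator (LSODA) with dense output evaluated on
    ``t_grid``, which must be nonempty, strictly increasing and start at 0.

    Raises
    ------
    RuntimeError
        On solver failure, reporting the time reached.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("t_grid must be nonempty")
    if t[0] != 0:
        raise ValueError("t_grid must start at 0")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if t.size == 1:
        return Trajectory(times=t, abundances=np.array([params.p0]))

    def rhs(_t, y):
        p = max(y[0], 0.0)
        return [params.alpha - params.mu * p - _degradation_rate(p, params.vmax, params.km)]

    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1])),
        [params.p0],
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed at t = {sol.t[-1] if sol.t.size else 0.0:.4g} h: "
            f"{sol.message}"
        )
    # Clip integrator noise below zero (abundance is a count).
    p = np.clip(sol.y[0], 0.0, None)
    return Trajectory(times=t, abundances=p)
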