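"""Core dynamic model: thermal growth responses, seasonal forcing, and the
network-coupled multi-taxon logistic ODE system.

Each taxon ``i`` follows

    dBi/dt = Ri(T(t)) * Bi * (1 - sum_j Bj / k) * (1 + sum_j eta_ij * Bj)

with a Gaussian thermal growth response ``R`` and sinusoidal temperature
forcing ``T``. The competition sum runs over all taxa (including ``i``);
the interaction matrix ``eta`` is supplied by network inference and its
diagonal is zero by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GrowthParams",
    "TemperatureProfile",
    "CommunityState",
    "Trajectory",
    "growth_rate",
    "temperature_at",
    "ode_rhs",
    "integrate",
    "relative_abundances",
    "phase_for_minimum_day",
]

DAYS_PER_YEAR = 365.0
ANNUAL_OMEGA = 2.0 * math.pi / DAYS_PER_YEAR

#: Default calendar day (mid-February) on which the annual temperature
#: minimum falls; used to pick the phase shift when none is given.
DEFAULT_MINIMUM_DAY = 45.0


def phase_for_minimum_day(day: float, omega: float = ANNUAL_OMEGA) -> float:
    """Phase shift placing the annual minimum of ``M + A sin(w t + theta)``
    at ``t = day``.

    The sine attains its minimum where ``w t + theta = -pi/2 (mod 2 pi)``.
    """
    theta = -math.pi / 2.0 - omega * day
    return math.remainder(theta, 2.0 * math.pi)


@dataclass(frozen=True)
class GrowthParams:
    """Per-taxon thermal growth response parameters.

    Parameters
    ----------
    taxon_id
        Label of the taxon.
    r_max
        Growth-rate scale in 1/day. Must be positive. Note that under the
        default ``density`` response form the peak rate is
        ``r_max / (sigma * sqrt(2 pi))``, not ``r_max`` itself.
    mu
        Mean ideal growth temperature in degrees Celsius.
    sigma
        Ideal-temperature range parameter in degrees Celsius. Must be
        positive.
    """

    taxon_id: str
    r_max: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r_max) and self.r_max > 0):
            raise ValueError(f"r_max must be positive, got {self.r_max!r}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma!r}")
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu!r}")


@dataclass(frozen=True)
class TemperatureProfile:
    """Sinusoidal seasonal forcing ``T(t) = M + A sin(omega t + theta)``.

    With ``amplitude == 0`` the profile is constant at ``mean_temp``.
    """

    mean_temp: float
    amplitude: float = 0.0
    omega: float = ANNUAL_OMEGA
    theta: float = field(
        default_factory=lambda: phase_for_minimum_day(DEFAULT_MINIMUM_DAY)
    )

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_temp):
            raise ValueError(f"mean_temp must be finite, got {self.mean_temp!r}")
        if not (np.isfinite(self.amplitude) and self.amplitude >= 0):
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude!r}")

    @property
    def period(self) -> float:
        """Forcing period in days (``inf`` for a constant profile)."""
        return 2.0 * math.pi / self.omega if self.omega != 0 else math.inf


@dataclass
class CommunityState:
    """Taxon abundances plus the shared carrying capacity."""

    abundances: np.ndarray
    carrying_capacity: float = 100.0

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 1:
            raise ValueError("abundances must be a 1-d vector")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        if not (np.isfinite(self.carrying_capacity) and self.carrying_capacity > 0):
            raise ValueError(
                f"carrying_capacity must be positive, got {self.carrying_capacity!r}"
            )

    @property
    def n_taxa(self) -> int:
        return self.abundances.size


@dataclass
class Trajectory:
    """Integration output: abundance matrix (time x taxon) on output times."""

    times: np.ndarray
    states: np.ndarray
    taxon_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape[0] != self.times.size:
            raise ValueError("states must have one row per output time")

    def state_at(self, t: float) -> np.ndarray:
        """Abundance vector at the output time closest to ``t``."""
        lo, hi = self.times[0], self.times[-1]
        if not (lo <= t <= hi):
            raise ValueError(f"t={t} outside trajectory range [{lo}, {hi}]")
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.states[idx]


ResponseForm = Literal["density", "peak"]


def growth_rate(
    params: GrowthParams,
    T: float | np.ndarray,
    response: ResponseForm = "density",
) -> float | np.ndarray:
    """Temperature-dependent growth rate for one taxon.

    The default ``density`` form is

        R(T) = r_max * (1 / sqrt(2 pi sigma^2)) * exp(-(T - mu)^2 / (2 sigma^2))

    i.e. ``r_max`` times a Gaussian density in ``T``, so the response
    integrates to ``r_max`` over all temperatures and peaks at
    ``r_max / (sigma sqrt(2 pi))``. The alternative ``peak`` form drops the
    normalizing constant so that ``R(mu) = r_max`` exactly.
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    z = (T - params.mu) / params.sigma
    bell = np.exp(-0.5 * z * z)
    if response == "density":
        rate = params.r_max * bell / (params.sigma * math.sqrt(2.0 * math.pi))
    elif response == "peak":
        rate = params.r_max * bell
    else:
        raise ValueError(f"unknown response form {response!r}")
    return rate if rate.ndim else float(rate)


def temperature_at(
    profile: TemperatureProfile, t: float | np.ndarray
) -> float | np.ndarray:
    """Evaluate ``T(t) = M + A sin(omega t + theta)`` at time ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    T = profile.mean_temp + profile.amplitude * np.sin(
        profile.omega * t + profile.theta
    )
    return T if T.ndim else float(T)


def _validate_dimensions(
    n: int, growth: Sequence[GrowthParams], eta: np.ndarray
) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if len(growth) != n:
        raise ValueError(f"{len(growth)} growth parameter sets for {n} taxa")
    if eta.shape != (n, n):
        raise ValueError(f"eta has shape {eta.shape}, expected {(n, n)}")
    return eta


def ode_rhs(
    t: float,
    state: CommunityState,
    growth: Sequence[GrowthParams],
    eta: np.ndarray,
    profile: TemperatureProfile,
    response: ResponseForm = "density",
) -> np.ndarray:
    """Right-hand side of the coupled community ODE at time ``t``.

    Component ``i`` is ``Ri(T(t)) * Bi * (1 - sum_j Bj/k) * (1 + sum_j
    eta_ij Bj)``; the competition sum includes ``i`` itself.
    """
    B = state.abundances
    eta = _validate_dimensions(B.size, growth, eta)
    T = temperature_at(profile, t)
    rates = np.array([growth_rate(g, T, response) for g in growth])
    competition = 1.0 - B.sum() / state.carrying_capacity
    interaction = 1.0 + eta @ B
    return rates * B * competition * interaction


def integrate(
    growth: Sequence[GrowthParams],
    eta: np.ndarray,
    profile: TemperatureProfile,
    init: CommunityState,
    t_span: tuple[float, float],
    output_times: np.ndarray | None = None,
    *,
    response: ResponseForm = "density",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the community ODE forward over ``t_span``.

    Output abundances in ``(-atol, 0)`` are clipped to zero; excursions
    below ``-atol`` indicate solver failure and raise.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise ValueError(f"t_span must be forward in time, got ({t0}, {t1})")
    n = init.n_taxa
    eta = _validate_dimensions(n, growth, eta)
    k = init.carrying_capacity
    r_arr = np.array([g.r_max for g in growth])
    mu_arr = np.array([g.mu for g in growth])
    sig_arr = np.array([g.sigma for g in growth])
    if response == "density":
        scale = r_arr / (sig_arr * math.sqrt(2.0 * math.pi))
    else:
        scale = r_arr

    def rhs(t: float, B: np.ndarray) -> np.ndarray:
        T = profile.mean_temp + profile.amplitude * math.sin(
            profile.omega * t + profile.theta
        )
        z = (T - mu_arr) / sig_arr
        rates = scale * np.exp(-0.5 * z * z)
        return rates * B * (1.0 - B.sum() / k) * (1.0 + eta @ B)

    if output_times is None:
        output_times = np.linspace(t0, t1, 201)
    output_times = np.asarray(output_times, dtype=float)

    sol = solve_ivp(
        rhs,
        (t0, t1),
        init.abundances,
        method=method,
        t_eval=output_times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed near t={sol.t[-1] if sol.t.size else t0}: {sol.message}")
    states = sol.y.T
    if np.any(states < -atol):
        worst = float(states.min())
        raise RuntimeError(f"negative abundance excursion {worst} below -atol")
    states = np.clip(states, 0.0, None)
    taxon_ids = [g.taxon_id for g in growth]
    return Trajectory(times=sol.t, states=states, taxon_ids=taxon_ids)


def relative_abundances(traj: Trajectory, t_sample: float) -> np.ndarray:
    """Percent composition of the community at time ``t_sample``.

    Returns a vector summing to 100. Raises if the community is entirely
    extinct at the sampling time (the composition would be undefined).
    """
    B = traj.state_at(t_sample)
    total = B.sum()
    if total <= 0:
        raise ValueError(f"all-zero community at t={t_sample}; composition undefined")
    return 100.0 * B / total
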