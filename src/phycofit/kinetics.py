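"""Closed-form and numeric kinetics of batch microalgal growth and lipid production.

The biomass obeys the logistic law

    dx/dt = k * x * (1 - x / xs)

with rate constant ``k`` (per unit time), carrying capacity ``xs`` (g/L,
the stationary-phase biomass) and initial concentration ``x0``.  Lipid
(product) formation follows the Luedeking-Piret law

    dp/dt = alpha * dx/dt + beta * x

splitting production into a growth-associated term (``alpha``, g product
per g new biomass) and a non-growth-associated term (``beta``, g product
per g biomass per unit time).

Both equations have exact solutions along the logistic trajectory; this
module provides the closed forms and, independently, a numeric
integration of the coupled system, so that either can check the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import solve_ivp

__all__ = [
    "LogisticParams",
    "LuedekingPiretParams",
    "Trajectory",
    "SimulationError",
    "logistic_rate",
    "logistic_solution",
    "lp_rate",
    "lp_integrated",
    "simulate",
]


class SimulationError(RuntimeError):
    """Numeric integration of the coupled system failed to converge."""


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic growth law.

    Attributes
    ----------
    x0 : float
        Initial biomass concentration (g/L), strictly positive.
    k : float
        Logistic rate constant (per unit time, conventionally h^-1).
    xs : float
        Stationary-phase biomass / carrying capacity (g/L).

    ``x0 > xs`` is rejected: the package models the growth regime only.
    ``x0 == xs`` is admitted (constant trajectory) but is rejected by the
    fitting layer, where it makes ``k`` unidentifiable.
    """

    x0: float
    k: float
    xs: float

    def __post_init__(self) -> None:
        if not (self.x0 > 0 and self.k > 0 and self.xs > 0):
            raise ValueError(
                f"x0, k, xs must all be positive; got x0={self.x0}, "
                f"k={self.k}, xs={self.xs}"
            )
        if self.x0 > self.xs:
            raise ValueError(
                f"x0={self.x0} exceeds carrying capacity xs={self.xs}; "
                "only the growth regime (x0 <= xs) is modelled"
            )


@dataclass(frozen=True)
class LuedekingPiretParams:
    """Parameters of the Luedeking-Piret product-formation law.

    Attributes
    ----------
    alpha : float
        Growth-associated coefficient (g product / g biomass), >= 0.
    beta : float
        Non-growth-associated coefficient (g product / g biomass / time), >= 0.
    p0 : float
        Initial product concentration (g/L), >= 0.
    """

    alpha: float
    beta: float
    p0: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.p0 < 0:
            raise ValueError(
                f"alpha, beta, p0 must be nonnegative; got alpha={self.alpha}, "
                f"beta={self.beta}, p0={self.p0}"
            )


@dataclass(frozen=True)
class Trajectory:
    """Biomass and product concentrations on a time grid."""

    times: NDArray[np.float64]
    biomass: NDArray[np.float64]
    product: NDArray[np.float64]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.biomass, dtype=float)
        p = np.asarray(self.product, dtype=float)
        if not (t.shape == x.shape == p.shape and t.ndim == 1):
            raise ValueError("times, biomass, product must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(x < 0) or np.any(p < 0):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "biomass", x)
        object.__setattr__(self, "product", p)


def _validate_times(times: ArrayLike) -> NDArray[np.float64]:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("time grid must be strictly increasing")
    if t.size and t[0] < 0:
        raise ValueError("time must be nonnegative")
    return t


def logistic_rate(x: ArrayLike, params: LogisticParams) -> NDArray[np.float64] | float:
    """Instantaneous logistic growth rate dx/dt = k*x*(1 - x/xs).

    Zero at both fixed points (x = 0 and x = xs), positive between them.
    """
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise ValueError("biomass concentration must be nonnegative")
    out = params.k * xv * (1.0 - xv / params.xs)
    return float(out) if np.isscalar(x) else out


def logistic_solution(
    t: ArrayLike, params: LogisticParams
) -> NDArray[np.float64] | float:
    """Closed-form logistic trajectory.

        x(t) = x0 * e^{kt} / (1 - (x0/xs) * (1 - e^{kt}))

    For 0 < x0 <= xs the denominator stays positive for all t >= 0, the
    curve is sigmoidal (lag, exponential, stationary) and saturates at xs.
    Evaluated in a form that avoids overflow of e^{kt} at large kt.
    """
    tv = np.asarray(t, dtype=float)
    if np.any(tv < 0):
        raise ValueError("time must be nonnegative")
    r = params.x0 / params.xs
    # x(t) = x0 / (e^{-kt} * (1 - r) + r); exp(-kt) underflows harmlessly.
    out = params.x0 / (np.exp(-params.k * tv) * (1.0 - r) + r)
    return float(out) if np.isscalar(t) else out


def lp_rate(
    growth_rate: ArrayLike, x: ArrayLike, params: LuedekingPiretParams
) -> NDArray[np.float64] | float:
    """Luedeking-Piret product rate dp/dt = alpha*dx/dt + beta*x."""
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise ValueError("biomass concentration must be nonnegative")
    out = params.alpha * np.asarray(growth_rate, dtype=float) + params.beta * xv
    return float(out) if np.isscalar(x) and np.isscalar(growth_rate) else out


def lp_integrated(
    t: ArrayLike, growth: LogisticParams, prod: LuedekingPiretParams
) -> NDArray[np.float64] | float:
    """Exact product concentration along the logistic trajectory.

        P(t) = p0 + alpha*(x(t) - x0) + beta*(xs/k)*ln[1 - (x0/xs)*(1 - e^{kt})]

    This is the analytic integral of the Luedeking-Piret rate with x(t)
    the logistic solution; differentiating recovers
    alpha*dx/dt + beta*x exactly.  The logarithmic term is evaluated as
    kt + ln(e^{-kt}*(1 - x0/xs) + x0/xs) so it cannot overflow.
    """
    tv = np.asarray(t, dtype=float)
    if np.any(tv < 0):
        raise ValueError("time must be nonnegative")
    r = growth.x0 / growth.xs
    x_t = growth.x0 / (np.exp(-growth.k * tv) * (1.0 - r) + r)
    # ln D(t) with D = 1 - r(1 - e^{kt}) = e^{kt} * (e^{-kt}(1-r) + r)
    log_term = growth.k * tv + np.log(np.exp(-growth.k * tv) * (1.0 - r) + r)
    out = (
        prod.p0
        + prod.alpha * (x_t - growth.x0)
        + prod.beta * (growth.xs / growth.k) * log_term
    )
    return float(out) if np.isscalar(t) else out


def simulate(
    growth: LogisticParams,
    prod: LuedekingPiretParams,
    times: ArrayLike,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Numerically integrate the coupled growth/production system.

    Solves dx/dt = k*x*(1 - x/xs), dp/dt = alpha*dx/dt + beta*x with an
    adaptive low-order Runge-Kutta pair (RK23), matching common
    bioprocess practice; the tight default tolerances make the result
    directly comparable with the closed forms.  The initial condition
    (x0, p0) is anchored at t = 0 so that the numeric trajectory shares
    the closed forms' time origin even when the grid starts later.

    Raises
    ------
    SimulationError
        If the solver fails, reporting the time it reached.
    """
    t = _validate_times(times)

    def rhs(_t: float, y: NDArray[np.float64]) -> list[float]:
        x = y[0]
        dx = growth.k * x * (1.0 - x / growth.xs)
        return [dx, prod.alpha * dx + prod.beta * x]

    t_end = float(t[-1])
    if t_end == 0.0:
        return Trajectory(
            times=t,
            biomass=np.full_like(t, growth.x0),
            product=np.full_like(t, prod.p0),
        )
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [growth.x0, prod.p0],
        method="RK23",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        reached = sol.t[-1] if sol.t.size else 0.0
        raise SimulationError(
            f"ODE solver failed near t={reached:g}: {sol.message}"
        )
    biomass = np.clip(sol.y[0], 0.0, None)
    product = np.clip(sol.y[1], 0.0, None)
    return Trajectory(times=t, biomass=biomass, product=product)
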