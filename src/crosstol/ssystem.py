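"""Pairwise power-law (S-system) kinetics for protein abundance time courses.

The model restricts the classical S-system to a single regulator per target:

    dX_t/dt = alpha * X_r(t)**g - beta * X_t**h

where ``X_r(t)`` is the regulator's abundance, reconstructed between sampled
time points by piecewise-linear interpolation, and ``X_t`` is the target.
``alpha`` and ``beta`` are nonnegative rate constants; ``g`` is the regulator
kinetic exponent (its sign encodes promotion vs. inhibition of production);
``h`` is the self-degradation exponent, fixed at 1 by default so that
degradation is first order.

Abundances are kept strictly positive: a floor of 1e-6 times the profile
maximum is applied before exponentiation so non-integer powers stay real.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Trajectory",
    "SSystemParams",
    "SSystemError",
    "DomainError",
    "ExtrapolationError",
    "IntegrationError",
    "NoSteadyStateError",
    "POSITIVITY_FLOOR_FRACTION",
    "simulate_pair",
    "steady_state",
]

#: Positivity floor, as a fraction of the profile maximum, applied before
#: raising abundances to non-integer powers.
POSITIVITY_FLOOR_FRACTION = 1e-6

G_BOUNDS = (-3.0, 3.0)
H_BOUNDS = (0.0, 3.0)


class SSystemError(Exception):
    """Base class for pairwise S-system failures."""


class DomainError(SSystemError, ValueError):
    """Input outside the model's domain (nonpositive abundance, bad bounds)."""


class ExtrapolationError(SSystemError, ValueError):
    """Requested times fall outside the regulator's observed span."""


class IntegrationError(SSystemError, RuntimeError):
    """The ODE integrator failed to advance the solution."""


class NoSteadyStateError(SSystemError, ValueError):
    """The pairwise ODE has no finite equilibrium (beta or h is zero)."""


@dataclass(frozen=True)
class Trajectory:
    """One protein's abundance time course under one cultivar/treatment.

    Times are in days; values are densitometric abundance units (arbitrary,
    nonnegative). Times must be strictly increasing and paired with values.
    """

    protein_id: str
    times: np.ndarray
    values: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise DomainError("times and values must be one-dimensional")
        if len(times) != len(values):
            raise DomainError(
                f"trajectory {self.protein_id!r}: {len(times)} times "
                f"but {len(values)} values"
            )
        if len(times) < 2:
            raise DomainError("a trajectory needs at least two time points")
        if not np.all(np.diff(times) > 0):
            raise DomainError("times must be strictly increasing")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise DomainError("values must be finite and nonnegative")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class SSystemParams:
    """Kinetic parameters of one candidate regulator→target interaction."""

    alpha: float
    beta: float
    g: float
    h: float = 1.0
    g_bounds: tuple[float, float] = field(default=G_BOUNDS, repr=False)

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise DomainError("alpha and beta must be nonnegative")
        lo, hi = self.g_bounds
        if not lo <= self.g <= hi:
            raise DomainError(f"g={self.g} outside bounds [{lo}, {hi}]")
        if not H_BOUNDS[0] <= self.h <= H_BOUNDS[1]:
            raise DomainError(f"h={self.h} outside bounds {H_BOUNDS}")


def simulate_pair(
    params: SSystemParams,
    regulator: Trajectory,
    x0: float,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the target profile driven by an observed regulator.

    Solves ``dX/dt = alpha * X_r(t)**g - beta * X**h`` from ``x0`` at
    ``times[0]``, where ``X_r(t)`` linearly interpolates the regulator's
    observed points, and returns the target values at the requested times.
    Output values are clipped below at the positivity floor.

    Parameters
    ----------
    params
        Kinetic parameters of the interaction.
    regulator
        Observed regulator time course; the requested times must lie within
        its span.
    x0
        Initial target abundance (must be positive).
    times
        Strictly increasing times at which to report the solution.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or not np.all(np.diff(times) > 0):
        raise DomainError("times must be a strictly increasing 1-d sequence")
    if not x0 > 0:
        raise DomainError(f"initial abundance must be positive, got {x0}")
    lo, hi = regulator.span
    if times[0] < lo - 1e-12 or times[-1] > hi + 1e-12:
        raise ExtrapolationError(
            f"requested times [{times[0]}, {times[-1]}] exceed the "
            f"regulator span [{lo}, {hi}]"
        )

    eps = POSITIVITY_FLOOR_FRACTION * max(float(regulator.values.max()), x0)
    reg_t = regulator.times
    reg_v = np.maximum(regulator.values, eps)
    alpha, beta, g, h = params.alpha, params.beta, params.g, params.h

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        xr = np.interp(t, reg_t, reg_v)
        xt = max(x[0], eps)
        return np.array([alpha * xr**g - beta * xt**h])

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        [float(x0)],
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed for alpha={alpha}, beta={beta}, g={g}, "
            f"h={h}: {sol.message}"
        )
    values = np.clip(sol.y[0], eps, None)
    return Trajectory(
        protein_id=f"sim[{regulator.protein_id}]",
        times=times,
        values=values,
        condition_label=regulator.condition_label,
    )


def steady_state(params: SSystemParams, regulator_value: float) -> float:
    """Equilibrium abundance of the pairwise ODE at a constant regulator level.

    Setting the rate to zero gives ``(alpha * x_r**g / beta) ** (1/h)``.
    """
    if params.beta == 0 or params.h == 0:
        raise NoSteadyStateError(
            "steady state requires beta > 0 and h > 0 "
            f"(got beta={params.beta}, h={params.h})"
        )
    if not regulator_value > 0:
        raise DomainError("regulator_value must be positive")
    return float(
        (params.alpha * regulator_value**params.g / params.beta)
        ** (1.0 / params.h)
    )
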