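"""Autocatalytic nucleation-elongation model of amyloid fibrillation.

The model describes amyloid-beta(1-42) assembly as two reactions: a slow,
first-order nucleation step (n monomers -> nucleus, rate constant ``kn``,
s^-1) followed by fast, aggregate-catalysed elongation (monomer + aggregate
-> longer aggregate, rate constant ``ke``, L mol^-1 s^-1).  With initial
monomer concentration ``a`` (mol/L) the fibrillar fraction f(t) obeys the
logistic-type rate law

    df/dt = k (1 - f) (rho + f),        f(0) = 0,

where k = ke * a sets the overall timescale and rho = kn / k controls how
pronounced the lag phase is (rho << 1 gives a long flat lag followed by a
steep growth phase).  The rate law integrates in closed form to

    f(t) = rho (exp[(1 + rho) k t] - 1) / (1 + rho exp[(1 + rho) k t]).

This module provides the parameter transforms between (kn, ke, a) and
(k, rho), a numerically stable closed-form evaluator, an independent ODE
integrator used as a cross-check oracle, and the derived half-time and
lag-time scales.  All times are seconds internally; unit conversion happens
at the I/O boundary.

The nucleus size n does not enter the closed form and is not a model
parameter here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticRates",
    "ReducedParams",
    "FractionCurve",
    "ReactionState",
    "ValidationError",
    "reduce_rates",
    "expand_params",
    "fibril_fraction",
    "ode_oracle",
    "half_time",
    "lag_time",
]


class ValidationError(ValueError):
    """Raised when a domain object or operation input violates its contract."""


@dataclass(frozen=True)
class KineticRates:
    """Physical rate constants of one aggregation condition.

    Parameters
    ----------
    kn : float
        Nucleation rate constant, s^-1.  Must be > 0.
    ke : float
        Elongation rate constant, L mol^-1 s^-1.  Must be > 0.
    a : float
        Initial monomer concentration, mol/L.  Must be > 0.
    """

    kn: float
    ke: float
    a: float

    def __post_init__(self) -> None:
        for name in ("kn", "ke", "a"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class ReducedParams:
    """Reduced parameterization (k, rho) of the autocatalytic model.

    ``k = ke * a`` (s^-1) is the combined growth rate; ``rho = kn / k`` is the
    dimensionless nucleation-to-growth ratio.  The physically typical regime
    is rho << 1 (slow nucleation, fast elongation).
    """

    k: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("k", "rho"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class FractionCurve:
    """A fibril-fraction time series: strictly increasing times (s), f in [0, 1]."""

    times: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.ndim != 1 or f.ndim != 1 or t.shape != f.shape:
            raise ValidationError("times and fractions must be 1-d arrays of equal length")
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValidationError("times must be >= 0 and strictly increasing")
        if np.any(f < 0) or np.any(f > 1) or not np.all(np.isfinite(f)):
            raise ValidationError("fractions must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ReactionState:
    """Conserved (monomer, fibril) fraction pair; the two must sum to 1."""

    monomer_fraction: float
    fibril_fraction: float

    def __post_init__(self) -> None:
        m, f = self.monomer_fraction, self.fibril_fraction
        if not (0 <= m <= 1 and 0 <= f <= 1):
            raise ValidationError("fractions must lie in [0, 1]")
        if abs(m + f - 1.0) > 1e-12:
            raise ValidationError("monomer_fraction + fibril_fraction must equal 1")


def reduce_rates(rates: KineticRates) -> ReducedParams:
    """Map physical constants (kn, ke, a) to the reduced pair (k, rho).

    k = ke * a and rho = kn / (ke * a).
    """
    k = rates.ke * rates.a
    return ReducedParams(k=k, rho=rates.kn / k)


def expand_params(params: ReducedParams, a: float) -> KineticRates:
    """Invert :func:`reduce_rates` at monomer concentration ``a`` (mol/L).

    ke = k / a and kn = rho * k; round-trips with reduce_rates to machine
    precision.
    """
    if not (math.isfinite(a) and a > 0):
        raise ValidationError(f"a must be finite and > 0, got {a!r}")
    return KineticRates(kn=params.rho * params.k, ke=params.k / a, a=a)


def fibril_fraction(params: ReducedParams, t):
    """Closed-form fibrillar fraction f(t) of the autocatalytic model.

    Evaluates f = rho (exp[u] - 1) / (1 + rho exp[u]) with u = (1 + rho) k t,
    written in the algebraically equivalent saturating form

        f = -rho * expm1(-u) / (exp(-u) + rho)

    which is overflow-free for arbitrarily large u and exact at u = 0.

    Parameters
    ----------
    params : ReducedParams
    t : float or array-like
        Time(s) in seconds, >= 0.

    Returns
    -------
    float or ndarray in [0, 1).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or not np.all(np.isfinite(t_arr)):
        raise ValidationError("t must be finite and >= 0")
    u = (1.0 + params.rho) * params.k * t_arr
    with np.errstate(over="ignore"):
        f = -params.rho * np.expm1(-u) / (np.exp(-u) + params.rho)
    return f if t_arr.ndim else float(f)


def ode_oracle(params: ReducedParams, times, rel_tol: float = 1e-8) -> FractionCurve:
    """Integrate df/dt = k(1-f)(rho+f), f(0)=0, as an independent cross-check.

    This solves the rate law of the two-step scheme (nucleation then
    aggregate-catalysed elongation) numerically, without using the closed
    form, so closed-form and oracle can be compared against each other.

    Parameters
    ----------
    times : array-like
        Strictly increasing evaluation times (s), >= 0.
    rel_tol : float
        Relative integration tolerance, in (0, 1e-3].

    Raises
    ------
    ValidationError
        On invalid inputs.
    RuntimeError
        If the integrator fails to converge (never silently truncated).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("times must be a non-empty 1-d array")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be >= 0 and strictly increasing")
    if not (0 < rel_tol <= 1e-3):
        raise ValidationError("rel_tol must lie in (0, 1e-3]")

    k, rho = params.k, params.rho

    def rhs(_t, f):
        return k * (1.0 - f) * (rho + f)

    # prepend t=0 so the initial condition anchors the solve
    needs_zero = t[0] > 0
    t_eval = np.concatenate(([0.0], t)) if needs_zero else t
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])) if t_eval[-1] > 0 else (0.0, 1.0),
        [0.0],
        t_eval=t_eval if t_eval[-1] > 0 else None,
        method="LSODA",
        rtol=rel_tol,
        atol=rel_tol * 1e-3,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    if t_eval[-1] == 0:  # times == [0]
        f = np.zeros_like(t)
    else:
        f = sol.y[0][1:] if needs_zero else sol.y[0]
    f = np.clip(f, 0.0, 1.0)
    return FractionCurve(times=t, fractions=f)


def half_time(params: ReducedParams) -> float:
    """Time at which f = 1/2: t50 = ln((1 + 2 rho)/rho) / ((1 + rho) k)."""
    return math.log((1.0 + 2.0 * params.rho) / params.rho) / ((1.0 + params.rho) * params.k)


def lag_time(params: ReducedParams) -> float | None:
    """Lag time by the tangent-at-maximum-slope construction; None if undefined.

    The growth rate df/dt = k(1-f)(rho+f) is maximal at f* = (1 - rho)/2,
    which is an interior point only for rho < 1; there the slope is
    k(1+rho)^2/4 and the inflection occurs at t* = ln(1/rho)/((1+rho)k).
    The lag time is where the tangent at the inflection crosses f = 0:

        t_lag = t* - f* / f'(t*)

    clamped below at 0 (for rho near 1 the construction can go negative).
    Returns None when rho >= 1 (no interior inflection, no lag phase).
    """
    k, rho = params.k, params.rho
    if rho >= 1.0:
        return None
    t_infl = math.log(1.0 / rho) / ((1.0 + rho) * k)
    f_infl = (1.0 - rho) / 2.0
    slope = k * (1.0 + rho) ** 2 / 4.0
    return max(0.0, t_infl - f_infl / slope)
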