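"""Nonlinear least-squares estimation of aggregation rate constants from
ThT fluorescence time courses.

ThT fluorescence at 483 nm is proportional to the amount of beta-sheet
fibrillar material, so an intensity trace F(t) is modelled as

    F(t) = F0 + dF * f(t; k, rho)

with baseline F0, amplitude dF, and f the closed-form fibrillar fraction of
the autocatalytic model.  The fit is a bounded trust-region least squares in
(ln k, ln rho, F0, dF): the two rate parameters span orders of magnitude and
must stay positive, so they are optimized on log scale.  Multi-start
restarts guard against the banana-shaped k-rho likelihood surface that
appears when the lag phase is nearly degenerate.

Fraction curves (already normalized to [0, 1]) are fitted with F0 = 0 and
dF = 1 held fixed.  Fitted (k, rho) are expanded back to (kn, ke) with the
supplied monomer concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    FractionCurve,
    KineticRates,
    ReducedParams,
    ValidationError,
    expand_params,
    fibril_fraction,
)

__all__ = [
    "ThTTimeCourse",
    "FitOptions",
    "FitResult",
    "NoSignalError",
    "fit_fraction_curve",
    "fit_intensity_curve",
    "initial_guess",
    "sigmoidality_check",
]

# bounds on ln k and ln rho; generous but finite so pinned parameters are detectable
_LOG_LO = math.log(1e-12)
_LOG_HI = math.log(1e3)


class NoSignalError(ValidationError):
    """Raised when a time course carries no aggregation signal to fit."""


@dataclass(frozen=True)
class ThTTimeCourse:
    """One ThT fluorescence trace: times (s, increasing), intensities (a.u. >= 0)."""

    times: np.ndarray
    intensities: np.ndarray
    condition: str = ""
    replicate: str = "mean"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValidationError("times and intensities must be 1-d arrays of equal length")
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValidationError("times must be >= 0 and strictly increasing")
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            raise ValidationError("intensities must be finite and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    restarts : multi-start count; each restart jitters the initial guess by a
        factor of up to 10 up or down on both rate parameters.
    ftol : convergence tolerance on the relative change in the sum of squares.
    max_iter : cap on residual evaluations per start.
    r2_threshold : minimum r-squared for a fit to be called sigmoidal.
    """

    restarts: int = 5
    ftol: float = 1e-10
    max_iter: int = 2000
    r2_threshold: float = 0.95
    seed: int = 0


@dataclass(frozen=True)
class FitResult:
    """Outcome of one curve fit.

    ``params`` holds the fitted (k, rho); ``rates`` the derived (kn, ke) at
    the supplied concentration, consistent via kn/(ke*a) == rho.  ``F0`` and
    ``dF`` are the fitted baseline and amplitude (fixed at 0 and 1 for
    fraction fits).  ``param_se`` are Gauss-Newton standard errors on (k, rho)
    or None when the Hessian approximation is singular.
    """

    params: ReducedParams
    rates: KineticRates
    F0: float
    dF: float
    sse: float
    r_squared: float
    converged: bool
    sigmoidal: bool
    param_se: tuple[float, float] | None = None
    reason: str = ""
    n_points: int = 0
    at_bound: bool = field(default=False, repr=False)

    def normalized_fraction(self, t):
        """The model fraction implied by the fit: (F(t) - F0)/dF."""
        return fibril_fraction(self.params, t)

    def to_dict(self) -> dict:
        return {
            "k_per_s": self.params.k,
            "rho": self.params.rho,
            "kn_per_s": self.rates.kn,
            "ke_per_M_s": self.rates.ke,
            "a_M": self.rates.a,
            "F0": self.F0,
            "dF": self.dF,
            "sse": self.sse,
            "r_squared": self.r_squared,
            "converged": self.converged,
            "sigmoidal": self.sigmoidal,
            "se_k": None if self.param_se is None else self.param_se[0],
            "se_rho": None if self.param_se is None else self.param_se[1],
            "reason": self.reason,
            "n_points": self.n_points,
        }


def initial_guess(curve: FractionCurve) -> ReducedParams:
    """Slope-based starting point for (k, rho).

    At the inflection the slope of f is k(1+rho)^2/4 ~= k/4 for small rho,
    so k0 = 4 * max discrete slope.  The initial slope is k*rho, so rho0 is
    the earliest positive discrete slope divided by k0.  Both are clipped
    into [1e-12, 1e3].

    Raises NoSignalError for a flat curve (no point above 20% of the final
    plateau level).
    """
    t, f = curve.times, curve.fractions
    if len(curve) < 2:
        raise NoSignalError("cannot initialize: need at least 2 points")
    plateau = f[-1]
    if plateau <= 0 or not np.any(f > 0.2 * plateau) or np.ptp(f) == 0:
        raise NoSignalError("cannot initialize: flat curve, no aggregation signal")
    slopes = np.diff(f) / np.diff(t)
    max_slope = float(np.max(slopes))
    if max_slope <= 0:
        raise NoSignalError("cannot initialize: no rising segment")
    k0 = 4.0 * max_slope
    pos = np.flatnonzero(slopes > 0)
    rho0 = float(slopes[pos[0]]) / k0
    clip = lambda x: float(np.clip(x, 1e-12, 1e3))
    return ReducedParams(k=clip(k0), rho=clip(rho0))


def _model_fraction(logk: float, logrho: float, t: np.ndarray) -> np.ndarray:
    return fibril_fraction(ReducedParams(k=math.exp(logk), rho=math.exp(logrho)), t)


def _run_starts(residual, x0, lo, hi, options: FitOptions, jitter_idx):
    """Multi-start bounded least squares; returns the lowest-SSE solution."""
    rng = np.random.default_rng(options.seed)
    best = None
    for start in range(max(1, options.restarts)):
        x = np.array(x0, dtype=float)
        if start > 0:
            x[jitter_idx] += rng.uniform(-math.log(10), math.log(10), size=len(jitter_idx))
        x = np.clip(x, lo, hi)
        try:
            sol = least_squares(
                residual,
                x,
                bounds=(lo, hi),
                method="trf",
                ftol=options.ftol,
                xtol=1e-14,
                gtol=1e-14,
                max_nfev=options.max_iter,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best


def _standard_errors(sol, n: int, p: int, k: float, rho: float):
    """Gauss-Newton SEs on (k, rho) from the log-scale Jacobian; None if singular."""
    if n <= p:
        return None
    sse = 2.0 * sol.cost
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (sse / (n - p))
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
        return None
    se_log = np.sqrt(np.diag(cov))
    # delta method: se(k) = k * se(ln k)
    return (k * float(se_log[0]), rho * float(se_log[1]))


def _r_squared(resid: np.ndarray, y: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    if sst == 0:
        return 0.0
    return 1.0 - sse / sst


def _near_bound(x: float, lo: float, hi: float, tol: float = 1e-6) -> bool:
    return (x - lo) < tol * (hi - lo) or (hi - x) < tol * (hi - lo)


def fit_fraction_curve(
    curve: FractionCurve, a: float, options: FitOptions | None = None
) -> FitResult:
    """Fit the closed-form model to a normalized fraction curve.

    F0 is fixed at 0 and dF at 1; only (k, rho) are free.  Raises
    NoSignalError on an all-zero or flat curve; reports converged=False
    honestly when the optimizer does not succeed.
    """
    options = options or FitOptions()
    if len(curve) < 5:
        raise ValidationError("need at least 5 points to fit a fraction curve")
    if not (a > 0):
        raise ValidationError("concentration a must be > 0")
    if np.ptp(curve.fractions) == 0:
        raise NoSignalError("no aggregation signal: constant fraction curve")

    guess = initial_guess(curve)
    t, f = curve.times, curve.fractions

    def residual(x):
        return _model_fraction(x[0], x[1], t) - f

    lo = np.array([_LOG_LO, _LOG_LO])
    hi = np.array([_LOG_HI, _LOG_HI])
    x0 = [math.log(guess.k), math.log(guess.rho)]
    sol = _run_starts(residual, x0, lo, hi, options, jitter_idx=[0, 1])

    k, rho = math.exp(sol.x[0]), math.exp(sol.x[1])
    params = ReducedParams(k=k, rho=rho)
    at_bound = any(_near_bound(sol.x[i], lo[i], hi[i]) for i in range(2))
    resid = residual(sol.x)
    r2 = _r_squared(resid, f)
    result = FitResult(
        params=params,
        rates=expand_params(params, a),
        F0=0.0,
        dF=1.0,
        sse=float(np.sum(resid**2)),
        r_squared=r2,
        converged=bool(sol.success),
        sigmoidal=True,
        param_se=_standard_errors(sol, len(curve), 2, k, rho),
        n_points=len(curve),
        at_bound=at_bound,
    )
    return sigmoidality_check(result, curve)[0]


def fit_intensity_curve(
    tc: ThTTimeCourse, a: float, options: FitOptions | None = None
) -> FitResult:
    """Fit F(t) = F0 + dF * f(t; k, rho) to a raw ThT intensity trace.

    All four parameters are free; with F0 = 0 and dF = 1 in the data this
    reduces to fit_fraction_curve on (k, rho).  A negative fitted amplitude
    (intensity decreasing over time) is flagged non-sigmoidal.
    """
    options = options or FitOptions()
    if len(tc) < 6:
        raise ValidationError("need at least 6 points to fit an intensity curve (4 free parameters)")
    if not (a > 0):
        raise ValidationError("concentration a must be > 0")
    t, y = tc.times, tc.intensities
    if np.ptp(y) == 0:
        raise NoSignalError("no aggregation signal: constant intensity trace")

    # normalize by the observed range to seed (k, rho)
    f_approx = np.clip((y - y.min()) / np.ptp(y), 0.0, 1.0)
    try:
        guess = initial_guess(FractionCurve(times=t, fractions=f_approx))
        F0_0, dF_0 = float(y.min()), float(np.ptp(y))
    except NoSignalError:
        # a falling trace normalizes to a mirrored sigmoid; seed from the
        # mirror and let the optimizer find the (negative-amplitude) best
        # fit, which sigmoidality_check will flag
        try:
            guess = initial_guess(FractionCurve(times=t, fractions=1.0 - f_approx))
        except NoSignalError:
            raise NoSignalError("no aggregation signal: no rising or falling transition")
        F0_0, dF_0 = float(y.max()), -float(np.ptp(y))
    span = max(np.ptp(y), 1.0)
    lo = np.array([_LOG_LO, _LOG_LO, y.min() - 10 * span, -10 * span])
    hi = np.array([_LOG_HI, _LOG_HI, y.max() + 10 * span, 10 * span])

    def residual(x):
        return x[2] + x[3] * _model_fraction(x[0], x[1], t) - y

    x0 = [math.log(guess.k), math.log(guess.rho), F0_0, dF_0]
    sol = _run_starts(residual, x0, lo, hi, options, jitter_idx=[0, 1])

    k, rho = math.exp(sol.x[0]), math.exp(sol.x[1])
    F0, dF = float(sol.x[2]), float(sol.x[3])
    params = ReducedParams(k=k, rho=rho)
    at_bound = any(_near_bound(sol.x[i], lo[i], hi[i]) for i in range(2))
    resid = residual(sol.x)
    se = _standard_errors(sol, len(tc), 4, k, rho)
    result = FitResult(
        params=params,
        rates=expand_params(params, a),
        F0=F0,
        dF=dF,
        sse=float(np.sum(resid**2)),
        r_squared=_r_squared(resid, y),
        converged=bool(sol.success),
        sigmoidal=True,
        param_se=se,
        n_points=len(tc),
        at_bound=at_bound,
    )
    return sigmoidality_check(result, tc)[0]


def sigmoidality_check(result: FitResult, curve) -> tuple[FitResult, str]:
    """Diagnose whether a completed fit describes a genuine sigmoidal transition.

    The fit is flagged non-sigmoidal when the amplitude is non-positive (the
    trace decreases), when r-squared falls below the threshold (default 0.95),
    or when a rate parameter sits on an optimizer bound.  Returns the
    (possibly re-flagged) result and the reason string.
    """
    reasons = []
    if result.dF <= 0:
        reasons.append(f"non-positive fitted amplitude dF={result.dF:.3g}")
    if result.r_squared < FitOptions().r2_threshold:
        reasons.append(f"r_squared={result.r_squared:.3f} below threshold 0.95")
    if result.at_bound:
        reasons.append("a rate parameter sits on an optimizer bound")
    reason = "; ".join(reasons)
    flagged = FitResult(
        params=result.params,
        rates=result.rates,
        F0=result.F0,
        dF=result.dF,
        sse=result.sse,
        r_squared=result.r_squared,
        converged=result.converged,
        sigmoidal=not reasons,
        param_se=result.param_se,
        reason=reason,
        n_points=result.n_points,
        at_bound=result.at_bound,
    )
    return flagged, reason
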