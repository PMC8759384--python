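"""Logistic accumulation model for per-stem dry matter and nitrogen.

A winter wheat stem accumulates above-ground dry matter (DMA, g stem⁻¹)
and nitrogen (NA, mg stem⁻¹) along a sigmoid trajectory that is well
described by the three-parameter logistic curve

    W(T) = W_max / (1 + a · e^(−k·T)),

where ``T`` is time in days after sowing, ``W_max`` the asymptotic
accumulation, ``a`` a dimensionless shape constant and ``k`` (d⁻¹) the
rate constant.

Setting the second and third derivatives of ``W`` to zero yields closed
forms for the *fast accumulation phase*: the inflection point

    Tm = ln(a) / k            (maximal instantaneous rate Vm = k·W_max/4),

and the phase boundaries

    T1 = ln(a / (2+√3)) / k,   T2 = ln(a / (2−√3)) / k,

between which the curve rises from W_max/(3+√3) to W_max/(3−√3); the mean
rate over the phase is Vt = (W2 − W1)/(T2 − T1) = W_max / (√3·(T2 − T1)).
These "eigenvalues" summarise when and how fast a treatment accumulates,
and are the quantities compared across sowing dates.

This module provides the curve itself, deterministic bounded nonlinear
least-squares fitting with a log-linearised initial guess, goodness of
fit, and the eigenvalue derivation.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GrowthModelError",
    "InvalidParameterError",
    "UndefinedPhaseError",
    "InitializationError",
    "InsufficientDataError",
    "UndefinedRSquaredError",
    "LogisticParams",
    "GrowthEigenvalues",
    "GrowthSeries",
    "FitResult",
    "logistic_value",
    "eigenvalues",
    "init_guess",
    "fit_logistic",
    "r_squared",
    "ROOT3",
    "FAST_PHASE_HALF_LOG",
]

logger = logging.getLogger(__name__)

ROOT3 = math.sqrt(3.0)
#: ln(2+√3); the fast phase spans ±this/k around Tm, so T2−T1 = 2·ln(2+√3)/k.
FAST_PHASE_HALF_LOG = math.log(2.0 + ROOT3)


class GrowthModelError(ValueError):
    """Base class for growth-curve errors."""


class InvalidParameterError(GrowthModelError):
    """Logistic parameters violate positivity/finiteness constraints."""


class UndefinedPhaseError(GrowthModelError):
    """Fast accumulation phase is not real-ordered (a ≤ 2−√3)."""


class InitializationError(GrowthModelError):
    """Log-linearised initial guess cannot be computed."""


class InsufficientDataError(GrowthModelError):
    """Too few distinct time points to fit three free parameters."""


class UndefinedRSquaredError(GrowthModelError):
    """R² undefined: zero variance in the observations."""


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of W(T) = w_max / (1 + a·exp(−k·T)).

    ``w_max`` carries the unit of the series (g stem⁻¹ for DMA, mg stem⁻¹
    for NA); ``a`` is dimensionless; ``k`` is per day. All three must be
    finite and strictly positive.
    """

    w_max: float
    a: float
    k: float

    def __post_init__(self) -> None:
        for name in ("w_max", "a", "k"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0.0):
                raise InvalidParameterError(
                    f"{name} must be finite and > 0, got {v!r}"
                )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_max, self.a, self.k)


@dataclass(frozen=True)
class GrowthEigenvalues:
    """Closed-form summary of the fast accumulation phase.

    Times are days after sowing; rates are accumulation units per day.
    ``duration`` is T2 − T1, the tables' "T"; ``w1``/``w2`` are the curve
    values at the phase boundaries.
    """

    t1: float
    t2: float
    duration: float
    tm: float
    vm: float
    vt: float
    w1: float
    w2: float


def logistic_value(params: LogisticParams, t):
    """Evaluate the logistic curve at time(s) ``t`` (days after sowing).

    ``t`` may be a scalar or array; negative values extrapolate before
    sowing. Returns values strictly inside (0, w_max).
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise GrowthModelError("t must be finite")
    with np.errstate(over="ignore"):
        out = params.w_max / (1.0 + params.a * np.exp(-params.k * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def eigenvalues(params: LogisticParams) -> GrowthEigenvalues:
    """Derive T1, T2, T (=T2−T1), Tm, Vm, Vt, W1, W2 from the parameters.

    Tm = ln(a)/k is the root of W''; T1, T2 = ln(a/(2±√3))/k are the roots
    of W'''. Raises :class:`UndefinedPhaseError` when a ≤ 2−√3, in which
    case T2 would precede time zero ordering of the log arguments.
    """
    w_max, a, k = params.as_tuple()
    if a <= 2.0 - ROOT3:
        raise UndefinedPhaseError(
            f"fast phase undefined for a={a!r} (requires a > 2-sqrt(3))"
        )
    tm = math.log(a) / k
    t1 = math.log(a / (2.0 + ROOT3)) / k
    t2 = math.log(a / (2.0 - ROOT3)) / k
    w1 = w_max / (3.0 + ROOT3)
    w2 = w_max / (3.0 - ROOT3)
    duration = t2 - t1
    vt = (w2 - w1) / duration
    vm = k * w_max / 4.0
    return GrowthEigenvalues(
        t1=t1, t2=t2, duration=duration, tm=tm, vm=vm, vt=vt, w1=w1, w2=w2
    )


@dataclass
class GrowthSeries:
    """Observed per-stem accumulation trajectory for one treatment.

    ``t`` holds days after sowing, ``w`` the per-stem accumulation in
    ``unit``; ``replicate`` optionally labels replicate observations at
    repeated times. Fitting consumes per-time replicate means.
    """

    season: str
    sowing_date: _dt.date | str
    variable: str  # "dma" | "na"
    unit: str  # "g_per_stem" | "mg_per_stem"
    t: np.ndarray
    w: np.ndarray
    replicate: np.ndarray | None = None
    stages: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.variable not in ("dma", "na"):
            raise GrowthModelError(f"variable must be 'dma' or 'na', got {self.variable!r}")
        if self.t.shape != self.w.shape or self.t.ndim != 1:
            raise GrowthModelError("t and w must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.w))):
            raise GrowthModelError("t and w must be finite")
        if np.any(self.t < 0):
            raise GrowthModelError("t must be >= 0 (days after sowing)")
        if np.any(self.w < 0):
            raise GrowthModelError("accumulation values must be >= 0")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.t.shape:
                raise GrowthModelError("replicate must match t in length")

    def aggregated(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-time replicate means, times strictly increasing."""
        tu, inverse = np.unique(self.t, return_inverse=True)
        sums = np.bincount(inverse, weights=self.w)
        counts = np.bincount(inverse)
        return tu, sums / counts

    @property
    def n_distinct_times(self) -> int:
        return int(np.unique(self.t).size)


@dataclass
class FitResult:
    """Outcome of a logistic fit: parameters, R², convergence, residuals."""

    params: LogisticParams
    r_squared: float
    converged: bool
    residuals: list[tuple[float, float]] = field(default_factory=list)
    message: str = ""
    n_points: int = 0


def _linearized_guess(t: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    w_max0 = 1.05 * float(np.max(w))
    usable = (w > 0.0) & (w < w_max0)
    if int(usable.sum()) < 2:
        raise InitializationError(
            "need >= 2 points with 0 < w < 1.05*max(w) for log-linearisation"
        )
    tu, wu = t[usable], w[usable]
    if np.ptp(wu) == 0.0:
        raise InitializationError("degenerate series: all usable observations equal")
    # ln(w_max0/w - 1) = ln(a) - k*t  -> ordinary least squares on t
    y = np.log(w_max0 / wu - 1.0)
    slope, intercept = np.polyfit(tu, y, 1)
    k0 = max(-float(slope), 1e-6)
    a0 = float(np.exp(intercept))
    return w_max0, a0, k0


def init_guess(series: GrowthSeries) -> LogisticParams:
    """Deterministic starting values from the log-linearised curve.

    Takes w_max₀ = 1.05·max(w), then regresses ln(w_max₀/w − 1) on t over
    the points strictly inside (0, w_max₀) to obtain a₀ = e^intercept and
    k₀ = −slope. No randomness is involved.
    """
    t, w = series.aggregated()
    if float(np.max(w, initial=0.0)) <= 0.0:
        raise InitializationError("all observations are zero")
    w_max0, a0, k0 = _linearized_guess(t, w)
    return LogisticParams(w_max=w_max0, a=a0, k=k0)


def fit_logistic(
    series: GrowthSeries,
    *,
    p0: LogisticParams | None = None,
    xtol: float = 1e-14,
    ftol: float = 1e-14,
    gtol: float = 1e-14,
    max_nfev: int = 20000,
) -> FitResult:
    """Bounded nonlinear least squares of the logistic curve on a series.

    Minimises Σ(w − W(t))² over (w_max, a, k) with all parameters bounded
    positive, starting from :func:`init_guess` unless ``p0`` is given.
    Deterministic given the data and options. Non-convergence is reported
    via ``converged=False`` and a warning, not an exception; fewer than 4
    distinct time points raises :class:`InsufficientDataError`.
    """
    t, w = series.aggregated()
    if t.size < 4:
        raise InsufficientDataError(
            f"{t.size} distinct time points; >= 4 required for 3 parameters"
        )
    if p0 is None:
        p0 = init_guess(series)

    def resid(x: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            return w - x[0] / (1.0 + x[1] * np.exp(-x[2] * t))

    lower = np.array([1e-12, 1e-12, 1e-12])
    x0 = np.clip(np.array(p0.as_tuple()), lower, None)
    # a spans many orders of magnitude; x_scale keeps the trust region sane
    sol = least_squares(
        resid,
        x0,
        bounds=(lower, np.inf),
        method="trf",
        x_scale=np.maximum(x0, 1e-6),
        xtol=xtol,
        ftol=ftol,
        gtol=gtol,
        max_nfev=max_nfev,
    )
    params = LogisticParams(*(float(v) for v in sol.x))
    converged = bool(sol.status > 0)
    if not converged:
        logger.warning(
            "logistic fit did not converge for %s/%s/%s: %s",
            series.season, series.sowing_date, series.variable, sol.message,
        )
    fitted = logistic_value(params, t)
    sse = float(np.sum((w - fitted) ** 2))
    sst = float(np.sum((w - w.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return FitResult(
        params=params,
        r_squared=r2,
        converged=converged,
        residuals=list(zip(t.tolist(), (w - fitted).tolist())),
        message=str(sol.message),
        n_points=int(t.size),
    )


def r_squared(fit: FitResult, series: GrowthSeries) -> float:
    """Coefficient of determination 1 − SSE/SST on per-time means."""
    t, w = series.aggregated()
    sst = float(np.sum((w - w.mean()) ** 2))
    if sst <= 0.0:
        raise UndefinedRSquaredError("zero variance in observations")
    fitted = logistic_value(fit.params, t)
    sse = float(np.sum((w - fitted) ** 2))
    return 1.0 - sse / sst
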