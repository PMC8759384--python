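"""Yield statistics for sowing-date trials.

Covers the percent yield loss relative to the normal sowing date,
pairwise treatment advantages, trait correlations, the loss-per-day
regression (three labelled variants, since the published procedure for
the per-day slope is not uniquely determined by treatment means), and the
linear regressions of grain yield on the mature/jointing accumulation
ratios (M_D/J_D for dry matter, M_N/J_N for nitrogen) with solving for
the ratio that sustains a target yield.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "YieldAnalysisError",
    "YieldRecord",
    "RatioPoint",
    "SeasonLine",
    "RatioRegressionResult",
    "LossRateEstimate",
    "yield_loss",
    "pct_advantage",
    "loss_per_day_regression",
    "pearson_r",
    "fit_ratio_regression",
    "threshold_from_lines",
    "productive_tiller_pct",
    "significance_stars",
]

logger = logging.getLogger(__name__)


class YieldAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class YieldRecord:
    """One plot's yield and yield components.

    grain_yield in kg ha⁻¹, spike_number in 10⁴ ha⁻¹, tkw = thousand-kernel
    weight in g.
    """

    season: str
    sowing_date: _dt.date | str
    grain_yield: float
    spike_number: float
    kernels_per_spike: float
    tkw: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for name in ("grain_yield", "spike_number", "kernels_per_spike", "tkw"):
            if getattr(self, name) <= 0:
                raise YieldAnalysisError(f"{name} must be > 0")


@dataclass(frozen=True)
class RatioPoint:
    """Mature/jointing accumulation ratio paired with plot yield."""

    season: str
    sowing_label: str
    ratio: float
    grain_yield: float

    def __post_init__(self) -> None:
        if self.ratio <= 1.0:
            logger.warning(
                "ratio %.3f <= 1 for %s/%s: accumulation normally grows past jointing",
                self.ratio, self.season, self.sowing_label,
            )


@dataclass(frozen=True)
class SeasonLine:
    """Per-season OLS line Y = slope·X + intercept with fit diagnostics."""

    season: str
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    threshold: float  # ratio solving target = slope*x + intercept


@dataclass(frozen=True)
class RatioRegressionResult:
    variable: str  # "dma" | "na"
    target_yield: float
    lines: tuple[SeasonLine, ...]
    threshold_ratio: float  # cross-season mean of per-season thresholds


@dataclass(frozen=True)
class LossRateEstimate:
    """Slope of percent yield loss per day of sowing-date displacement."""

    method: str
    slope: float  # % per day
    intercept: float
    se_slope: float
    n: int


def yield_loss(y_ns: float, y: float) -> float:
    """Percent yield loss (y_ns − y)/y_ns × 100 vs the normal sowing date.

    Negative when the treatment out-yields the normal date.
    """
    if y_ns <= 0:
        raise YieldAnalysisError(f"normal-sowing yield must be > 0, got {y_ns!r}")
    return (y_ns - y) / y_ns * 100.0


def pct_advantage(
    yields_a: Mapping[str, float],
    yields_b: Mapping[str, float],
) -> float:
    """Mean percent by which treatment A out-yields B across seasons.

    ``yields_a``/``yields_b`` map season → mean grain yield; the advantage
    (Y_A/Y_B − 1)×100 is computed per season, then averaged.
    """
    missing = set(yields_a) ^ set(yields_b)
    if missing:
        raise YieldAnalysisError(f"seasons not shared by both treatments: {sorted(missing)}")
    if not yields_a:
        raise YieldAnalysisError("no seasons provided")
    per_season = [(yields_a[s] / yields_b[s] - 1.0) * 100.0 for s in yields_a]
    return float(np.mean(per_season))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value (t, n−2 df)."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.size != y_arr.size or x_arr.size < 3:
        raise YieldAnalysisError("need equal-length samples with n >= 3")
    if np.ptp(x_arr) == 0 or np.ptp(y_arr) == 0:
        raise YieldAnalysisError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x_arr, y_arr)
    return float(res.statistic), float(res.pvalue)


def _ols_with_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """slope, intercept, SE(slope) by the normal equations."""
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise YieldAnalysisError("zero variance in predictor")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    dof = n - 2
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else float("nan")
    return slope, intercept, se


def loss_per_day_regression(
    yields: Mapping[str, Mapping[str, float]],
    offsets: Mapping[str, float],
    normal: str,
    method: str = "pooled_ols",
) -> LossRateEstimate:
    """Regress percent yield loss on days of displacement from normal sowing.

    ``yields`` maps season → {sowing label → mean yield}; ``offsets`` maps
    sowing label → signed days from the normal date. Losses are computed
    with :func:`yield_loss` against the normal treatment of the same
    season and regressed on |offset|.

    Three variants are supported, because the published per-day slope is a
    figure-level fit whose exact construction is not recoverable from the
    printed treatment means; results carry their method label and none is
    claimed to match the published value:

    - ``pooled_ols``: one OLS line (with intercept) over all seasons;
    - ``per_season_ols_mean``: per-season OLS slopes, averaged;
    - ``through_origin``: pooled no-intercept fit, slope = Σxy/Σx².
    """
    if normal not in offsets:
        raise YieldAnalysisError(f"normal treatment {normal!r} missing from offsets")
    seasons = list(yields)
    pts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for season in seasons:
        by_label = yields[season]
        if normal not in by_label:
            raise YieldAnalysisError(f"normal treatment missing in season {season!r}")
        xs, ys = [], []
        for label, y_val in by_label.items():
            if label not in offsets:
                raise YieldAnalysisError(f"no sowing offset for treatment {label!r}")
            xs.append(abs(float(offsets[label])))
            ys.append(yield_loss(by_label[normal], y_val))
        if len(xs) < 3:
            raise YieldAnalysisError("need >= 3 sowing dates per season")
        pts[season] = (np.asarray(xs), np.asarray(ys))

    x_all = np.concatenate([pts[s][0] for s in seasons])
    y_all = np.concatenate([pts[s][1] for s in seasons])
    if method == "pooled_ols":
        slope, intercept, se = _ols_with_intercept(x_all, y_all)
        return LossRateEstimate("pooled_ols", slope, intercept, se, x_all.size)
    if method == "per_season_ols_mean":
        slopes, ses = [], []
        for season in seasons:
            s, _, e = _ols_with_intercept(*pts[season])
            slopes.append(s)
            ses.append(e)
        return LossRateEstimate(
            "per_season_ols_mean",
            float(np.mean(slopes)),
            float("nan"),
            float(np.std(slopes, ddof=1) / np.sqrt(len(slopes))) if len(slopes) > 1 else float("nan"),
            x_all.size,
        )
    if method == "through_origin":
        sxx = float(np.sum(x_all**2))
        if sxx == 0:
            raise YieldAnalysisError("all offsets zero")
        slope = float(np.sum(x_all * y_all) / sxx)
        resid = y_all - slope * x_all
        dof = x_all.size - 1
        se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else float("nan")
        return LossRateEstimate("through_origin", slope, 0.0, se, x_all.size)
    raise YieldAnalysisError(f"unknown method {method!r}")


def _solve_threshold(slope: float, intercept: float, target: float) -> float:
    if slope == 0:
        raise YieldAnalysisError("zero slope: target ratio undefined")
    return (target - intercept) / slope


def fit_ratio_regression(
    points: Iterable[RatioPoint],
    *,
    variable: str = "dma",
    target: float = 6000.0,
) -> RatioRegressionResult:
    """Per-season OLS of grain yield on the mature/jointing ratio.

    Fits Y = slope·X + intercept within each season (≥ 3 points each),
    solves slope·x + intercept = target for the season's threshold ratio,
    and reports the cross-season mean threshold — the ratio at which the
    target yield (default 6000 kg ha⁻¹) is sustained.
    """
    by_season: dict[str, list[RatioPoint]] = {}
    for p in points:
        by_season.setdefault(p.season, []).append(p)
    if not by_season:
        raise YieldAnalysisError("no ratio points provided")
    lines: list[SeasonLine] = []
    for season in sorted(by_season):
        pts = by_season[season]
        if len(pts) < 3:
            raise YieldAnalysisError(f"season {season!r} has {len(pts)} points; >= 3 required")
        x = np.array([p.ratio for p in pts])
        y = np.array([p.grain_yield for p in pts])
        res = stats.linregress(x, y)
        lines.append(
            SeasonLine(
                season=season,
                slope=float(res.slope),
                intercept=float(res.intercept),
                r=float(res.rvalue),
                p=float(res.pvalue),
                n=len(pts),
                threshold=_solve_threshold(float(res.slope), float(res.intercept), target),
            )
        )
    mean_threshold = float(np.mean([ln.threshold for ln in lines]))
    return RatioRegressionResult(
        variable=variable,
        target_yield=target,
        lines=tuple(lines),
        threshold_ratio=mean_threshold,
    )


def threshold_from_lines(
    lines: Mapping[str, tuple[float, float]],
    target: float = 6000.0,
) -> tuple[float, dict[str, float]]:
    """Threshold ratios from already-fitted (slope, intercept) lines.

    ``lines`` maps season → (slope, intercept). Returns the cross-season
    mean threshold and the per-season thresholds. This is the
    coefficients-only path used when regression lines are given directly
    rather than refit from points.
    """
    if not lines:
        raise YieldAnalysisError("no regression lines provided")
    per_season = {
        season: _solve_threshold(slope, intercept, target)
        for season, (slope, intercept) in lines.items()
    }
    return float(np.mean(list(per_season.values()))), per_season


def productive_tiller_pct(peak: float, at_maturity: float) -> float:
    """Percentage of peak tillers that bear spikes at maturity."""
    if peak <= 0:
        raise YieldAnalysisError("peak tiller count must be > 0")
    if at_maturity < 0 or at_maturity > peak:
        raise YieldAnalysisError("require 0 <= at_maturity <= peak")
    return at_maturity / peak * 100.0


def significance_stars(p: float) -> str:
    """Two-tier convention: '**' for p<0.01, '*' for p<0.05, '' otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
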