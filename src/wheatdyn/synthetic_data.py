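"""Synthetic sowing-date experiments with known ground truth.

Raw per-stem trajectories of the reference trial were never deposited, so
pipeline testing relies on generated experiments that emulate the study's
structure: a shared daily weather realisation per season (sinusoidal
annual cycle with a winter trough plus AR(1) noise), four sowing dates,
phenology stages placed where thermal time from sowing crosses configured
thresholds, six-point logistic growth trajectories per treatment and
variable with multiplicative log-normal observation noise, and plot
yields linear in the dry-matter mature/jointing ratio. Every generated
quantity is recorded as ground truth so each analysis stage can be
checked for exact recovery at zero noise and for calibration under noise.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth_curve import GrowthSeries, LogisticParams, logistic_value
from .phenothermal import (
    PhenologyRecord,
    WeatherSeries,
    accumulated_temperature,
    treatment_label,
    wintering_onset,
)
from .yield_analysis import YieldRecord

__all__ = [
    "GenerationError",
    "WeatherConfig",
    "GrowthRanges",
    "SamplingConfig",
    "YieldModelConfig",
    "SyntheticConfig",
    "SyntheticExperiment",
    "gen_weather",
    "gen_growth_series",
    "gen_yields",
    "make_experiment",
]


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class WeatherConfig:
    """Sinusoid + AR(1) daily temperature model with a winter trough.

    ``annual_mean``/``amplitude`` (°C) put the sinusoid minimum
    (annual_mean − amplitude) at ``trough_month_day``; ``noise_sd`` (°C)
    and ``ar1`` control the day-to-day anomaly process; ``diurnal_half_range``
    sets t_min/t_max = t_mean ∓/± that amount.
    """

    annual_mean: float = 16.0
    amplitude: float = 10.0
    trough_month_day: tuple[int, int] = (1, 15)
    noise_sd: float = 1.5
    ar1: float = 0.6
    diurnal_half_range: float = 4.0
    rain_prob: float = 0.3
    rain_mean_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")
        if not (0.0 <= self.ar1 < 1.0):
            raise GenerationError("ar1 must be in [0, 1)")


@dataclass(frozen=True)
class GrowthRanges:
    """Uniform sampling envelopes for one variable's logistic truth.

    The inflection time tm is drawn instead of the shape constant a
    (a = e^(k·tm)), which keeps curves in a realistic window; k must stay
    within (0.05, 0.15) d⁻¹.
    """

    w_max: tuple[float, float]
    k: tuple[float, float]
    tm: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("w_max", "k", "tm"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise GenerationError(f"{name} range must be ordered, got ({lo}, {hi})")
        if not (0.05 < self.k[0] and self.k[1] < 0.15):
            raise GenerationError("k range must lie strictly inside (0.05, 0.15)")


@dataclass(frozen=True)
class SamplingConfig:
    """Where growth is sampled and how noisy the observations are.

    Stages are placed where thermal time from sowing (base 0 °C) crosses
    the configured thresholds (°C·d); one extra early-tillering point at
    ``early_point_day`` days after sowing completes the six fitted points.
    ``noise_sd`` is the standard deviation of log-normal multiplicative
    observation noise.
    """

    stage_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {
            "wintering": 350.0,
            "jointing": 1000.0,
            "booting": 1250.0,
            "flowering": 1450.0,
            "maturity": 2150.0,
        }
    )
    early_point_day: int = 15
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")
        thr = list(self.stage_thresholds.values())
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise GenerationError("stage thresholds must be strictly increasing")


@dataclass(frozen=True)
class YieldModelConfig:
    """Per-season linear yield model Y = slope·ratio + intercept + noise."""

    lines: tuple[tuple[float, float], ...] = ((306.03, 4511.69), (636.93, 3924.05))
    noise_sd: float = 150.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")
        for slope, intercept in self.lines:
            if not (math.isfinite(slope) and math.isfinite(intercept)):
                raise GenerationError("yield model coefficients must be finite")


@dataclass(frozen=True)
class SyntheticConfig:
    """Complete recipe for one synthetic sowing-date experiment."""

    seed: int
    n_seasons: int = 2
    first_season_start_year: int = 2018
    sowing_month_days: tuple[tuple[int, int], ...] = (
        (10, 28),
        (11, 5),
        (11, 13),
        (11, 21),
    )
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    growth: Mapping[str, GrowthRanges] = field(
        default_factory=lambda: {
            "dma": GrowthRanges(w_max=(3.0, 3.9), k=(0.070, 0.100), tm=(134.0, 156.0)),
            "na": GrowthRanges(w_max=(44.0, 54.0), k=(0.072, 0.111), tm=(123.0, 143.0)),
        }
    )
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    yield_model: YieldModelConfig = field(default_factory=YieldModelConfig)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise GenerationError("seed is mandatory and must be an integer")
        if self.n_seasons < 1:
            raise GenerationError("n_seasons must be >= 1")
        if self.n_seasons > len(self.yield_model.lines):
            raise GenerationError("need one yield-model line per season")

    def season_label(self, i: int) -> str:
        y = self.first_season_start_year + i
        return f"{y}-{y + 1}"

    def zero_noise(self) -> "SyntheticConfig":
        """Copy with every stochastic component switched off."""
        return dataclasses.replace(
            self,
            weather=dataclasses.replace(self.weather, noise_sd=0.0),
            sampling=dataclasses.replace(self.sampling, noise_sd=0.0),
            yield_model=dataclasses.replace(self.yield_model, noise_sd=0.0),
        )


@dataclass
class SyntheticExperiment:
    """Generated dataset plus the ground truth that produced it."""

    config: SyntheticConfig
    weather: dict[str, WeatherSeries]
    phenology: list[PhenologyRecord]
    growth: list[GrowthSeries]
    yields: list[YieldRecord]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write weather/phenology/growth/yield CSVs and truth JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        frames = []
        for season, ws in sorted(self.weather.items()):
            df = ws.frame.reset_index(names="date")
            df.insert(0, "season", season)
            df["date"] = df["date"].dt.strftime("%Y-%m-%d")
            frames.append(df[["season", "date", "t_min", "t_mean", "t_max", "precipitation"]])
        paths["weather"] = out / "weather.csv"
        pd.concat(frames).to_csv(paths["weather"], index=False)

        pheno = pd.DataFrame(
            [
                {
                    "season": r.season,
                    "sowing_date": r.sowing_date.isoformat(),
                    "stage": r.stage,
                    "date": r.date.isoformat(),
                }
                for r in self.phenology
            ]
        )
        paths["phenology"] = out / "phenology.csv"
        pheno.to_csv(paths["phenology"], index=False)

        rows = []
        for g in self.growth:
            stages = g.stages if g.stages is not None else [""] * g.t.size
            for stage, t, w in zip(stages, g.t, g.w):
                rows.append(
                    {
                        "season": g.season,
                        "sowing_date": g.sowing_date.isoformat()
                        if isinstance(g.sowing_date, _dt.date)
                        else g.sowing_date,
                        "stage": stage,
                        "days_after_sowing": int(t),
                        "variable": g.variable,
                        "value": w,
                        "replicate": 1,
                    }
                )
        paths["growth"] = out / "growth.csv"
        pd.DataFrame(rows).to_csv(paths["growth"], index=False, float_format="%.8g")

        ydf = pd.DataFrame(
            [
                {
                    "season": y.season,
                    "sowing_date": y.sowing_date.isoformat()
                    if isinstance(y.sowing_date, _dt.date)
                    else y.sowing_date,
                    "grain_yield": y.grain_yield,
                    "spike_number": y.spike_number,
                    "kernels_per_spike": y.kernels_per_spike,
                    "tkw": y.tkw,
                    "replicate": y.replicate,
                }
                for y in self.yields
            ]
        )
        paths["yield"] = out / "yield.csv"
        ydf.to_csv(paths["yield"], index=False, float_format="%.6f")

        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return paths


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *[int(t) for t in tags]])


def gen_weather(config: SyntheticConfig, season_index: int) -> WeatherSeries:
    """Daily weather for one season: sinusoid + AR(1) anomalies.

    The series runs 1 Oct of the season's start year through 15 Jul of the
    next year, so it brackets sowing and maturity with margin, and its
    deterministic part dips below 10 °C in winter (wintering exists).
    """
    wc = config.weather
    year = config.first_season_start_year + season_index
    dates = pd.date_range(_dt.date(year, 10, 1), _dt.date(year + 1, 7, 15), freq="D")
    trough = pd.Timestamp(
        _dt.date(year + 1, wc.trough_month_day[0], wc.trough_month_day[1])
    )
    delta = (dates - trough).days.astype(float)
    base = wc.annual_mean - wc.amplitude * np.cos(2.0 * np.pi * delta / 365.25)

    rng = _rng(config.seed, 1, season_index)
    n = dates.size
    eps = np.zeros(n)
    if wc.noise_sd > 0:
        z = rng.standard_normal(n)
        innovation_sd = wc.noise_sd * math.sqrt(1.0 - wc.ar1**2)
        eps[0] = wc.noise_sd * z[0]
        for i in range(1, n):
            eps[i] = wc.ar1 * eps[i - 1] + innovation_sd * z[i]
    else:
        rng.standard_normal(n)  # keep stream alignment across noise settings
    t_mean = base + eps
    wet = rng.random(n) < wc.rain_prob
    precip = np.where(wet, rng.exponential(wc.rain_mean_mm, n), 0.0)
    return WeatherSeries.from_arrays(
        season=config.season_label(season_index),
        dates=[d.date() for d in dates],
        t_min=t_mean - wc.diurnal_half_range,
        t_mean=t_mean,
        t_max=t_mean + wc.diurnal_half_range,
        precipitation=precip,
    )


def gen_growth_series(
    truth: LogisticParams,
    stage_days: Sequence[float],
    noise_sd: float,
    seed: int | np.random.Generator,
    *,
    season: str = "synthetic",
    sowing_date: _dt.date | str = "synthetic",
    variable: str = "dma",
    stages: Sequence[str] | None = None,
) -> GrowthSeries:
    """Sample a logistic trajectory at the stage days with log-normal noise.

    Observations are w_i = W(t_i)·exp(ε_i), ε ~ N(0, noise_sd²) — noise is
    multiplicative because per-stem accumulation is positive and spans
    orders of magnitude between tillering and maturity.
    """
    days = np.asarray(stage_days, dtype=float)
    if days.size < 4:
        raise GenerationError(f"{days.size} stage days; >= 4 required for fitting")
    if np.any(np.diff(days) <= 0):
        raise GenerationError("stage days must be strictly increasing")
    if noise_sd < 0:
        raise GenerationError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(0.0, 1.0, days.size) * noise_sd
    clean = logistic_value(truth, days)
    return GrowthSeries(
        season=season,
        sowing_date=sowing_date,
        variable=variable,
        unit="g_per_stem" if variable == "dma" else "mg_per_stem",
        t=days,
        w=clean * np.exp(eps),
        stages=list(stages) if stages is not None else None,
    )


def gen_yields(
    ratios: Mapping[str, float],
    model: tuple[float, float, float],
    seed: int | np.random.Generator,
    *,
    season: str = "synthetic",
    sowing_dates: Mapping[str, _dt.date] | None = None,
    n_replicates: int = 3,
) -> list[YieldRecord]:
    """Plot yields linear in the accumulation ratio, with Gaussian noise.

    ``ratios`` maps treatment label → mature/jointing ratio; ``model`` is
    (slope, intercept, noise_sd). Yield components are generated as
    plausible correlates of the plot yield (they are reported, not
    asserted against any model).
    """
    slope, intercept, sd = model
    if not (math.isfinite(slope) and math.isfinite(intercept)):
        raise GenerationError("slope and intercept must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[YieldRecord] = []
    for label in sorted(ratios):
        mean_yield = slope * ratios[label] + intercept
        for rep in range(1, n_replicates + 1):
            y = mean_yield + rng.normal(0.0, 1.0) * sd
            if y <= 0:
                raise GenerationError(
                    f"non-positive yield generated for {label!r}; lower noise_sd"
                )
            kernels = float(np.clip(rng.normal(40.0, 1.5), 30.0, 50.0))
            tkw = float(np.clip(rng.normal(44.0, 2.0), 35.0, 55.0))
            spikes = y / (0.87 * kernels * tkw * 0.01)
            records.append(
                YieldRecord(
                    season=season,
                    sowing_date=sowing_dates[label] if sowing_dates else label,
                    grain_yield=float(y),
                    spike_number=float(spikes),
                    kernels_per_spike=kernels,
                    tkw=tkw,
                    replicate=rep,
                )
            )
    return records


def _stage_day(
    weather: WeatherSeries, sowing: _dt.date, threshold: float
) -> int:
    """Days after sowing at which cumulative thermal time crosses threshold."""
    window = weather.frame.loc[pd.Timestamp(sowing) :]
    cumulative = np.cumsum(np.maximum(window["t_mean"].values, 0.0))
    idx = int(np.searchsorted(cumulative, threshold))
    if idx >= cumulative.size:
        raise GenerationError(
            f"thermal threshold {threshold} °C·d never reached after sowing {sowing} "
            f"(season ends at {weather.end} with {cumulative[-1]:.0f} °C·d)"
        )
    return idx


def make_experiment(config: SyntheticConfig) -> SyntheticExperiment:
    """Compose weather, phenology, growth and yields into one experiment.

    One weather realisation per season is shared by all sowing dates
    (matching the field design); each treatment's stages fall where its
    own thermal-time clock crosses the configured thresholds, so delayed
    sowing propagates into compressed phenology.
    """
    weather: dict[str, WeatherSeries] = {}
    phenology: list[PhenologyRecord] = []
    growth: list[GrowthSeries] = []
    yields: list[YieldRecord] = []
    truth: dict = {
        "seed": int(config.seed),
        "params": {},
        "stage_days": {},
        "wintering_onset": {},
        "thermal_to_wintering": {},
        "yield_model": {},
        "ratios": {},
    }

    for i in range(config.n_seasons):
        season = config.season_label(i)
        ws = gen_weather(config, i)
        weather[season] = ws
        year = config.first_season_start_year + i
        slope, intercept = config.yield_model.lines[i]
        truth["yield_model"][season] = {"slope": slope, "intercept": intercept}

        season_ratios: dict[str, float] = {}
        sowing_by_label: dict[str, _dt.date] = {}
        for j, (month, day) in enumerate(config.sowing_month_days):
            sowing = _dt.date(year, month, day)
            label = treatment_label(sowing)
            sowing_by_label[label] = sowing

            onset = wintering_onset(ws, sowing)
            if onset is None and "wintering" in config.sampling.stage_thresholds:
                raise GenerationError(
                    f"no wintering onset after sowing {sowing}: weather too warm "
                    "for the requested wintering stage"
                )
            truth["wintering_onset"].setdefault(season, {})[label] = (
                onset.isoformat() if onset else None
            )
            if onset is not None and onset > sowing:
                ttw = accumulated_temperature(ws, sowing, onset - _dt.timedelta(days=1))
            else:
                ttw = 0.0
            truth["thermal_to_wintering"].setdefault(season, {})[label] = ttw

            stage_days: dict[str, int] = {}
            phenology.append(PhenologyRecord(season, sowing, "sowing", sowing))
            for stage, threshold in config.sampling.stage_thresholds.items():
                d = _stage_day(ws, sowing, threshold)
                stage_days[stage] = d
                phenology.append(
                    PhenologyRecord(season, sowing, stage, sowing + _dt.timedelta(days=d))
                )
            truth["stage_days"].setdefault(season, {})[label] = stage_days

            sample_days = [config.sampling.early_point_day] + list(stage_days.values())
            sample_stages = ["early"] + list(stage_days.keys())
            order = np.argsort(sample_days)
            sample_days = [sample_days[o] for o in order]
            sample_stages = [sample_stages[o] for o in order]
            if len(set(sample_days)) != len(sample_days):
                raise GenerationError(
                    f"duplicate sampling days {sample_days} for sowing {sowing}"
                )

            for v, variable in enumerate(sorted(config.growth)):
                ranges = config.growth[variable]
                prng = _rng(config.seed, 2, i, j, v)
                w_max = prng.uniform(*ranges.w_max)
                k = prng.uniform(*ranges.k)
                tm = prng.uniform(*ranges.tm)
                params = LogisticParams(w_max=w_max, a=math.exp(k * tm), k=k)
                truth["params"].setdefault(season, {}).setdefault(label, {})[variable] = {
                    "w_max": w_max,
                    "a": params.a,
                    "k": k,
                    "tm": tm,
                }
                growth.append(
                    gen_growth_series(
                        params,
                        sample_days,
                        config.sampling.noise_sd,
                        _rng(config.seed, 3, i, j, v),
                        season=season,
                        sowing_date=sowing,
                        variable=variable,
                        stages=sample_stages,
                    )
                )
                if variable == "dma":
                    ratio = logistic_value(params, stage_days["maturity"]) / logistic_value(
                        params, stage_days["jointing"]
                    )
                    season_ratios[label] = float(ratio)

        truth["ratios"][season] = season_ratios
        yields.extend(
            gen_yields(
                season_ratios,
                (slope, intercept, config.yield_model.noise_sd),
                _rng(config.seed, 4, i),
                season=season,
                sowing_dates=sowing_by_label,
                n_replicates=config.yield_model.n_replicates,
            )
        )

    return SyntheticExperiment(
        config=config,
        weather=weather,
        phenology=phenology,
        growth=growth,
        yields=yields,
        truth=truth,
    )
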