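"""Weather-derived phenology and thermal-time statistics.

Sowing-date treatments of winter wheat differ mainly through the weather
window each one experiences: thermal time (growing degree days, base 0 °C
by default) accumulated before the onset of wintering, the length of the
sowing→flowering and grain-filling phases, and the mean temperature during
filling. This module computes those summaries from a daily weather series
plus observed stage dates, and the cross-sowing-date contrasts (per-season
deltas averaged across seasons).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenoThermalError",
    "DateRangeError",
    "WeatherSeries",
    "PhenologyRecord",
    "SeasonThermalSummary",
    "DurationDelta",
    "ThermalReduction",
    "STAGES",
    "accumulated_temperature",
    "wintering_onset",
    "cold_period_length",
    "mean_filling_temperature",
    "build_summary",
    "duration_deltas",
    "thermal_reduction_pct",
    "treatment_label",
]

#: Recognised growth stages in phenological order.
STAGES = ("sowing", "wintering", "jointing", "booting", "flowering", "maturity")


class PhenoThermalError(ValueError):
    pass


class DateRangeError(PhenoThermalError):
    """Requested dates fall outside the weather series."""


def treatment_label(sowing_date: _dt.date | str) -> str:
    """Cross-season treatment label, e.g. ``date(2018, 10, 28) -> '28-Oct'``.

    Sowing-date treatments repeat the same month-day in every season, so
    the day-month string identifies a treatment across seasons. Strings
    are passed through unchanged (already labels).
    """
    if isinstance(sowing_date, str):
        return sowing_date
    return f"{sowing_date.day}-{sowing_date.strftime('%b')}"


@dataclass
class WeatherSeries:
    """Consecutive daily weather records for one growing season.

    ``frame`` is indexed by a gap-free daily DatetimeIndex with columns
    ``t_min``, ``t_mean``, ``t_max`` (°C) and ``precipitation`` (mm).
    """

    season: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"t_min", "t_mean", "t_max", "precipitation"}
        missing = required - set(df.columns)
        if missing:
            raise PhenoThermalError(f"weather frame missing columns: {sorted(missing)}")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise PhenoThermalError("weather frame must have a DatetimeIndex")
        if len(df) == 0:
            raise PhenoThermalError("weather frame is empty")
        diffs = np.diff(df.index.values).astype("timedelta64[D]").astype(int)
        if np.any(diffs != 1):
            raise PhenoThermalError("weather dates must be consecutive daily records")
        if np.any(df["t_min"].values > df["t_mean"].values + 1e-9) or np.any(
            df["t_mean"].values > df["t_max"].values + 1e-9
        ):
            raise PhenoThermalError("require t_min <= t_mean <= t_max on every day")

    @classmethod
    def from_arrays(
        cls,
        season: str,
        dates: Sequence[_dt.date],
        t_min: Sequence[float],
        t_mean: Sequence[float],
        t_max: Sequence[float],
        precipitation: Sequence[float] | None = None,
    ) -> "WeatherSeries":
        n = len(dates)
        frame = pd.DataFrame(
            {
                "t_min": np.asarray(t_min, dtype=float),
                "t_mean": np.asarray(t_mean, dtype=float),
                "t_max": np.asarray(t_max, dtype=float),
                "precipitation": (
                    np.zeros(n) if precipitation is None else np.asarray(precipitation, dtype=float)
                ),
            },
            index=pd.DatetimeIndex(pd.to_datetime(list(dates))),
        )
        return cls(season=season, frame=frame)

    @property
    def start(self) -> _dt.date:
        return self.frame.index[0].date()

    @property
    def end(self) -> _dt.date:
        return self.frame.index[-1].date()

    def _slice(self, start: _dt.date, end: _dt.date) -> pd.DataFrame:
        if start > end:
            raise DateRangeError(f"start {start} after end {end}")
        if start < self.start or end > self.end:
            raise DateRangeError(
                f"[{start}, {end}] outside weather series [{self.start}, {self.end}]"
            )
        return self.frame.loc[pd.Timestamp(start) : pd.Timestamp(end)]


@dataclass(frozen=True)
class PhenologyRecord:
    """Observed calendar date of a growth stage for one treatment."""

    season: str
    sowing_date: _dt.date
    stage: str
    date: _dt.date

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise PhenoThermalError(f"unknown stage {self.stage!r}; expected one of {STAGES}")


@dataclass(frozen=True)
class SeasonThermalSummary:
    """Per-treatment growth-time and thermal statistics for one season."""

    season: str
    sowing_label: str
    days_sowing_to_flowering: float
    filling_days: float
    accumulated_temperature_whole: float
    thermal_time_sowing_to_wintering: float
    mean_filling_temperature: float

    @property
    def growth_duration(self) -> float:
        """Sowing to end of filling, in days."""
        return self.days_sowing_to_flowering + self.filling_days


def accumulated_temperature(
    weather: WeatherSeries,
    start: _dt.date,
    end: _dt.date,
    base: float = 0.0,
) -> float:
    """Thermal time Σ max(t_mean − base, 0) over [start, end], both inclusive."""
    window = weather._slice(start, end)
    return float(np.maximum(window["t_mean"].values - base, 0.0).sum())


def _run_starts_and_lengths(below: np.ndarray) -> list[tuple[int, int]]:
    """(start index, length) of each maximal run of True values."""
    runs: list[tuple[int, int]] = []
    i, n = 0, below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def wintering_onset(
    weather: WeatherSeries,
    after: _dt.date,
    threshold: float = 10.0,
    run: int = 3,
) -> _dt.date | None:
    """First date ≥ ``after`` starting ≥ ``run`` consecutive days below ``threshold``.

    Wintering is taken to begin with the first cold spell: a run of at
    least ``run`` days (default 3) with mean temperature below
    ``threshold`` (default 10 °C). Returns ``None`` when no qualifying
    spell exists in the series.
    """
    window = weather._slice(after, weather.end)
    below = window["t_mean"].values < threshold
    for start_idx, length in _run_starts_and_lengths(below):
        if length >= run:
            return window.index[start_idx].date()
    return None


def cold_period_length(
    weather: WeatherSeries,
    threshold: float = 10.0,
    run: int = 3,
) -> int:
    """Total days in cold spells of ≥ ``run`` consecutive sub-threshold days."""
    below = weather.frame["t_mean"].values < threshold
    return int(sum(length for _, length in _run_starts_and_lengths(below) if length >= run))


def mean_filling_temperature(
    weather: WeatherSeries,
    flowering: _dt.date,
    end_filling: _dt.date,
) -> float:
    """Arithmetic mean of daily mean temperature over [flowering, end_filling]."""
    if flowering >= end_filling:
        raise PhenoThermalError("flowering must precede end of filling")
    window = weather._slice(flowering, end_filling)
    return float(window["t_mean"].values.mean())


def build_summary(
    weather: WeatherSeries,
    phenology: Iterable[PhenologyRecord],
    *,
    base: float = 0.0,
    wintering_threshold: float = 10.0,
    wintering_run: int = 3,
) -> SeasonThermalSummary:
    """Assemble the season summary for one treatment from weather + stage dates.

    Requires sowing, flowering and maturity records. The wintering bound is
    detected from weather (first qualifying cold spell after sowing); the
    thermal time from sowing to wintering sums up to the day *before* the
    onset, since the onset day is already cold.
    """
    dates: dict[str, _dt.date] = {}
    season = weather.season
    sowing_date: _dt.date | None = None
    for rec in phenology:
        dates[rec.stage] = rec.date
        sowing_date = rec.sowing_date
    for stage in ("sowing", "flowering", "maturity"):
        if stage not in dates:
            raise PhenoThermalError(f"phenology missing required stage {stage!r}")
    sowing, flowering, maturity = dates["sowing"], dates["flowering"], dates["maturity"]
    onset = wintering_onset(weather, sowing, wintering_threshold, wintering_run)
    if onset is None:
        raise PhenoThermalError(f"no wintering onset found after {sowing} in {season}")
    if onset > sowing:
        ttw = accumulated_temperature(weather, sowing, onset - _dt.timedelta(days=1), base)
    else:
        ttw = 0.0
    return SeasonThermalSummary(
        season=season,
        sowing_label=treatment_label(sowing_date if sowing_date is not None else sowing),
        days_sowing_to_flowering=float((flowering - sowing).days),
        filling_days=float((maturity - flowering).days),
        accumulated_temperature_whole=accumulated_temperature(weather, sowing, maturity, base),
        thermal_time_sowing_to_wintering=ttw,
        mean_filling_temperature=mean_filling_temperature(weather, flowering, maturity),
    )


def _by_treatment(
    summaries: Iterable[SeasonThermalSummary],
) -> dict[str, dict[str, SeasonThermalSummary]]:
    out: dict[str, dict[str, SeasonThermalSummary]] = {}
    for s in summaries:
        out.setdefault(s.sowing_label, {})[s.season] = s
    return out


@dataclass(frozen=True)
class DurationDelta:
    """Per-treatment reductions vs the reference sowing date, in days."""

    sowing_label: str
    flowering_advance_days: float  # cross-season mean reduction in sowing→flowering
    duration_reduction_days: float  # cross-season mean reduction in total duration
    per_season_flowering: Mapping[str, float]
    per_season_duration: Mapping[str, float]


@dataclass(frozen=True)
class ThermalReduction:
    """Percent reduction in pre-wintering thermal time vs the reference."""

    sowing_label: str
    mean_pct: float
    rounded_pct: int
    per_season_pct: Mapping[str, float]


def _round_half_up(x: float, ndigits: int = 0) -> float:
    from .report import round_half_up

    return round_half_up(x, ndigits)


def duration_deltas(
    summaries: Iterable[SeasonThermalSummary],
    reference: str,
) -> dict[str, DurationDelta]:
    """Flowering advance and growth-duration shortening vs a reference date.

    For each non-reference treatment, computes per-season
    (reference − treatment) differences in days-sowing-to-flowering and in
    total growth duration (days to flowering + filling days), then averages
    across seasons. Deltas are positive when delay shortens the phase.
    """
    groups = _by_treatment(summaries)
    if reference not in groups:
        raise PhenoThermalError(f"reference treatment {reference!r} absent from summaries")
    ref = groups[reference]
    out: dict[str, DurationDelta] = {}
    for label, per_season in groups.items():
        missing = set(ref) - set(per_season)
        if missing:
            raise PhenoThermalError(f"treatment {label!r} missing seasons {sorted(missing)}")
        flowering = {
            season: ref[season].days_sowing_to_flowering - per_season[season].days_sowing_to_flowering
            for season in ref
        }
        duration = {
            season: ref[season].growth_duration - per_season[season].growth_duration
            for season in ref
        }
        out[label] = DurationDelta(
            sowing_label=label,
            flowering_advance_days=float(np.mean(list(flowering.values()))),
            duration_reduction_days=float(np.mean(list(duration.values()))),
            per_season_flowering=flowering,
            per_season_duration=duration,
        )
    return out


def thermal_reduction_pct(
    summaries: Iterable[SeasonThermalSummary],
    reference: str,
) -> dict[str, ThermalReduction]:
    """Percent loss of sowing→wintering thermal time relative to a reference.

    Percentages are computed per season as (ref − treat)/ref × 100 and then
    averaged across seasons; both the raw mean and its half-up integer
    rounding are reported.
    """
    groups = _by_treatment(summaries)
    if reference not in groups:
        raise PhenoThermalError(f"reference treatment {reference!r} absent from summaries")
    ref = groups[reference]
    out: dict[str, ThermalReduction] = {}
    for label, per_season in groups.items():
        missing = set(ref) - set(per_season)
        if missing:
            raise PhenoThermalError(f"treatment {label!r} missing seasons {sorted(missing)}")
        pct: dict[str, float] = {}
        for season in ref:
            denom = ref[season].thermal_time_sowing_to_wintering
            if denom <= 0:
                raise PhenoThermalError(f"zero reference thermal time in {season}")
            pct[season] = (
                (denom - per_season[season].thermal_time_sowing_to_wintering) / denom * 100.0
            )
        mean_pct = float(np.mean(list(pct.values())))
        out[label] = ThermalReduction(
            sowing_label=label,
            mean_pct=mean_pct,
            rounded_pct=int(_round_half_up(mean_pct, 0)),
            per_season_pct=pct,
        )
    return out
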