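"""CSV readers and writers for the trial data dialects.

Weather:   season(optional),date,t_min,t_max,t_mean(optional),precipitation
Phenology: season,sowing_date,stage,date
Growth:    season,sowing_date,stage,days_after_sowing,variable,value,replicate
Yield:     season,sowing_date,grain_yield,spike_number,kernels_per_spike,tkw,replicate

Dates are ISO-8601. Missing t_mean is filled with (t_min+t_max)/2 and
logged. Malformed input raises :class:`CsvFormatError` naming the column.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_curve import GrowthSeries
from .phenothermal import PhenologyRecord, WeatherSeries
from .yield_analysis import YieldRecord

__all__ = [
    "CsvFormatError",
    "read_weather",
    "read_phenology",
    "read_growth",
    "read_yield",
]

logger = logging.getLogger(__name__)


class CsvFormatError(ValueError):
    pass


def _require(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CsvFormatError(f"{path}: missing required column(s) {missing}")


def _parse_dates(series: pd.Series, column: str, path: str | Path) -> pd.Series:
    try:
        return pd.to_datetime(series, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise CsvFormatError(f"{path}: column {column!r} has a malformed date: {exc}") from exc


def read_weather(path: str | Path) -> dict[str, WeatherSeries]:
    """Read daily weather, one series per season."""
    df = pd.read_csv(path)
    _require(df, ["date", "t_min", "t_max", "precipitation"], path)
    if "season" not in df.columns:
        df["season"] = "all"
    if "t_mean" not in df.columns or df["t_mean"].isna().any():
        logger.info("%s: t_mean absent/incomplete; filling with (t_min+t_max)/2", path)
        filled = (df["t_min"] + df["t_max"]) / 2.0
        df["t_mean"] = df["t_mean"].fillna(filled) if "t_mean" in df.columns else filled
    df["date"] = _parse_dates(df["date"], "date", path)
    out: dict[str, WeatherSeries] = {}
    for season, grp in df.groupby("season", sort=True):
        grp = grp.sort_values("date").set_index("date")
        out[str(season)] = WeatherSeries(
            season=str(season),
            frame=grp[["t_min", "t_mean", "t_max", "precipitation"]],
        )
    return out


def read_phenology(path: str | Path) -> list[PhenologyRecord]:
    df = pd.read_csv(path)
    _require(df, ["season", "sowing_date", "stage", "date"], path)
    df["sowing_date"] = _parse_dates(df["sowing_date"], "sowing_date", path)
    df["date"] = _parse_dates(df["date"], "date", path)
    return [
        PhenologyRecord(
            season=str(r.season),
            sowing_date=r.sowing_date.date(),
            stage=str(r.stage),
            date=r.date.date(),
        )
        for r in df.itertuples()
    ]


def read_growth(path: str | Path) -> list[GrowthSeries]:
    """Read growth observations grouped into one series per
    (season, sowing date, variable)."""
    df = pd.read_csv(path)
    _require(df, ["season", "sowing_date", "days_after_sowing", "variable", "value"], path)
    df["sowing_date"] = _parse_dates(df["sowing_date"], "sowing_date", path)
    bad = ~df["variable"].isin(["dma", "na"])
    if bad.any():
        raise CsvFormatError(
            f"{path}: column 'variable' must be 'dma' or 'na', "
            f"got {sorted(df.loc[bad, 'variable'].unique())}"
        )
    if not np.issubdtype(df["value"].dtype, np.number):
        raise CsvFormatError(f"{path}: column 'value' must be numeric")
    series: list[GrowthSeries] = []
    for (season, sowing, variable), grp in df.groupby(
        ["season", "sowing_date", "variable"], sort=True
    ):
        grp = grp.sort_values("days_after_sowing")
        series.append(
            GrowthSeries(
                season=str(season),
                sowing_date=sowing.date(),
                variable=str(variable),
                unit="g_per_stem" if variable == "dma" else "mg_per_stem",
                t=grp["days_after_sowing"].to_numpy(dtype=float),
                w=grp["value"].to_numpy(dtype=float),
                replicate=grp["replicate"].to_numpy() if "replicate" in grp else None,
                stages=grp["stage"].astype(str).tolist() if "stage" in grp else None,
            )
        )
    return series


def read_yield(path: str | Path) -> list[YieldRecord]:
    df = pd.read_csv(path)
    _require(
        df,
        ["season", "sowing_date", "grain_yield", "spike_number", "kernels_per_spike", "tkw"],
        path,
    )
    df["sowing_date"] = _parse_dates(df["sowing_date"], "sowing_date", path)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return [
        YieldRecord(
            season=str(r.season),
            sowing_date=r.sowing_date.date(),
            grain_yield=float(r.grain_yield),
            spike_number=float(r.spike_number),
            kernels_per_spike=float(r.kernels_per_spike),
            tkw=float(r.tkw),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]
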