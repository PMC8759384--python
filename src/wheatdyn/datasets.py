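"""Published summary data from a two-season winter wheat sowing-date trial.

The reference dataset comes from a field experiment on the Jianghan Plain
(middle-lower Yangtze River Basin, cv. Zhengmai 9023) with four sowing
dates — 28 Oct (early), 5 Nov (normal), 13 Nov (late), 21 Nov (latest) —
repeated over the 2018-2019 and 2019-2020 growing seasons. Only treatment
-level summaries were published (fitted logistic coefficients, growth-time
and thermal statistics, yield means, yield-vs-ratio regression lines);
raw trajectories were not. These tables serve as inputs for the
closed-form eigenvalue derivation and the derived statistics, and as the
oracle against which the published eigenvalue tables are reproduced.
"""

from __future__ import annotations

import io

import pandas as pd

from .phenothermal import SeasonThermalSummary

__all__ = [
    "SOWING_LABELS",
    "SEASONS",
    "SOWING_OFFSETS",
    "NORMAL_SOWING",
    "EARLIEST_SOWING",
    "fit_coefficients",
    "published_eigenvalues",
    "growth_time_summary",
    "thermal_summaries",
    "yield_components",
    "tiller_counts",
    "ratio_regression_lines",
]

SEASONS = ("2018-2019", "2019-2020")
SOWING_LABELS = ("28-Oct", "5-Nov", "13-Nov", "21-Nov")
#: Signed days from the earliest sowing date (28-Oct).
SOWING_OFFSETS = {"28-Oct": 0, "5-Nov": 8, "13-Nov": 16, "21-Nov": 24}
NORMAL_SOWING = "5-Nov"
EARLIEST_SOWING = "28-Oct"

# Fitted logistic coefficients W = w_max/(1 + a*exp(-k*t)) per treatment
# and variable (dma in g/stem, na in mg/stem), with reported R².
_FIT_COEFFICIENTS_CSV = """\
season,sowing_label,variable,w_max,a,k,r_squared
2018-2019,28-Oct,dma,3.6217,4101240.31,0.0976,0.9941
2018-2019,5-Nov,dma,3.0897,420518907.20,0.1339,0.9909
2018-2019,13-Nov,dma,3.5946,45779.88,0.0701,0.9992
2018-2019,21-Nov,dma,3.9149,48761.68,0.0722,0.9995
2019-2020,28-Oct,dma,3.1812,109524.11,0.0862,0.9925
2019-2020,5-Nov,dma,3.1866,91308.58,0.0836,0.9949
2019-2020,13-Nov,dma,3.0814,20681.61,0.0734,0.9977
2019-2020,21-Nov,dma,3.2251,10799.99,0.0692,0.9981
2018-2019,28-Oct,na,44.2207,436306.39,0.0906,0.9808
2018-2019,5-Nov,na,44.6148,839280.29,0.0960,0.9874
2018-2019,13-Nov,na,46.4937,1030959.01,0.0986,0.9932
2018-2019,21-Nov,na,50.2932,3464573.17,0.1109,0.9980
2019-2020,28-Oct,na,44.8498,28575.36,0.0834,0.9787
2019-2020,5-Nov,na,51.9671,12335.05,0.0724,0.9782
2019-2020,13-Nov,na,52.0154,12551.56,0.0741,0.9838
2019-2020,21-Nov,na,54.2685,62975.43,0.0888,0.9872
"""

# Published fast-phase eigenvalues derived from the same fits:
# t1/t2/duration/tm in days (1 decimal), vt/vm in accumulation units per
# day (2 decimals).
_PUBLISHED_EIGENVALUES_CSV = """\
season,sowing_label,variable,t1,t2,duration,vt,tm,vm
2018-2019,28-Oct,dma,142.5,169.5,27.0,0.08,156.0,0.09
2018-2019,5-Nov,dma,138.5,158.2,19.7,0.09,148.4,0.10
2018-2019,13-Nov,dma,134.2,171.8,37.5,0.06,153.0,0.06
2018-2019,21-Nov,dma,131.4,167.9,36.5,0.06,149.6,0.07
2019-2020,28-Oct,dma,119.4,150.0,30.6,0.06,134.7,0.07
2019-2020,5-Nov,dma,120.9,152.4,31.5,0.06,136.6,0.07
2019-2020,13-Nov,dma,117.4,153.3,35.9,0.05,135.4,0.06
2019-2020,21-Nov,dma,115.3,153.3,38.1,0.05,134.3,0.06
2018-2019,28-Oct,na,128.8,157.9,29.1,0.88,143.3,1.00
2018-2019,5-Nov,na,128.4,155.8,27.4,0.94,142.1,1.07
2018-2019,13-Nov,na,127.0,153.7,26.7,1.01,140.4,1.15
2018-2019,21-Nov,na,123.9,147.7,23.8,1.22,135.8,1.39
2019-2020,28-Oct,na,107.3,138.8,31.6,0.82,123.1,0.93
2019-2020,5-Nov,na,111.9,148.3,36.4,0.82,130.1,0.94
2019-2020,13-Nov,na,109.6,145.1,35.5,0.85,127.3,0.96
2019-2020,21-Nov,na,109.6,139.3,29.7,1.06,124.5,1.20
"""

# Growth-time and meteorological statistics per treatment: days from
# sowing to flowering, filling-stage length (d), accumulated temperature
# over the whole growth period (°C d), thermal time sowing→wintering
# (°C d), mean daily temperature during filling (°C).
_GROWTH_TIME_CSV = """\
season,sowing_label,days_to_flowering,filling_days,accum_temp_whole,thermal_to_wintering,mean_filling_temp
2018-2019,28-Oct,164,38,2141.2,623.0,20.08
2018-2019,5-Nov,159,37,2048.6,486.2,20.28
2018-2019,13-Nov,153,36,1978.9,397.6,20.48
2018-2019,21-Nov,149,36,1985.2,310.2,20.71
2019-2020,28-Oct,146,50,2304.6,741.6,17.93
2019-2020,5-Nov,143,46,2187.1,601.6,18.23
2019-2020,13-Nov,142,43,2140.7,469.3,19.84
2019-2020,21-Nov,138,39,2028.8,357.4,20.25
"""

# Treatment-mean grain yield (kg/ha), spike number (1e4/ha), kernels per
# spike, thousand-kernel weight (g).
_YIELD_CSV = """\
season,sowing_label,grain_yield,spike_number,kernels_per_spike,tkw
2018-2019,28-Oct,6403.8,444.0,40.8,40.5
2018-2019,5-Nov,6578.9,484.3,37.8,40.6
2018-2019,13-Nov,5674.8,437.7,37.9,40.9
2018-2019,21-Nov,5569.7,371.7,41.0,41.1
2019-2020,28-Oct,6980.0,432.0,40.9,46.9
2019-2020,5-Nov,7241.7,466.7,38.9,47.2
2019-2020,13-Nov,5958.3,411.7,40.5,47.7
2019-2020,21-Nov,5625.0,391.3,42.0,48.1
"""

# Tiller counts (no./m²) at jointing and maturity, the seasonal peak, and
# the published productive-tiller percentage.
_TILLER_CSV = """\
season,sowing_label,jointing,maturity,peak,productive_pct
2018-2019,28-Oct,530.67,444.00,785.33,56.65
2018-2019,5-Nov,636.00,484.33,754.67,64.23
2018-2019,13-Nov,596.00,437.67,596.00,73.45
2018-2019,21-Nov,640.00,371.67,640.00,58.33
2019-2020,28-Oct,524.00,432.00,1078.67,40.06
2019-2020,5-Nov,642.33,466.67,876.00,53.48
2019-2020,13-Nov,660.00,411.67,660.00,62.38
2019-2020,21-Nov,701.33,391.33,701.33,55.80
"""

# Published per-season regression lines of grain yield (kg/ha) on the
# mature/jointing accumulation ratio, Y = slope*X + intercept.
_RATIO_LINES = {
    "dma": {"2018-2019": (306.03, 4511.69), "2019-2020": (636.93, 3924.05)},
    "na": {"2018-2019": (698.98, 3904.74), "2019-2020": (1273.29, 3485.91)},
}


def _read(csv_text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(csv_text))


def fit_coefficients() -> pd.DataFrame:
    """Published logistic fit coefficients per (season, sowing date, variable)."""
    return _read(_FIT_COEFFICIENTS_CSV)


def published_eigenvalues() -> pd.DataFrame:
    """Published fast-phase eigenvalue tables (printed precision)."""
    return _read(_PUBLISHED_EIGENVALUES_CSV)


def growth_time_summary() -> pd.DataFrame:
    """Published growth-time and thermal statistics per treatment."""
    return _read(_GROWTH_TIME_CSV)


def thermal_summaries() -> list[SeasonThermalSummary]:
    """Growth-time statistics as :class:`SeasonThermalSummary` objects."""
    return [
        SeasonThermalSummary(
            season=row.season,
            sowing_label=row.sowing_label,
            days_sowing_to_flowering=float(row.days_to_flowering),
            filling_days=float(row.filling_days),
            accumulated_temperature_whole=float(row.accum_temp_whole),
            thermal_time_sowing_to_wintering=float(row.thermal_to_wintering),
            mean_filling_temperature=float(row.mean_filling_temp),
        )
        for row in growth_time_summary().itertuples()
    ]


def yield_components() -> pd.DataFrame:
    """Treatment-mean grain yield and yield components."""
    return _read(_YIELD_CSV)


def tiller_counts() -> pd.DataFrame:
    """Tiller counts and productive-tiller percentages."""
    return _read(_TILLER_CSV)


def ratio_regression_lines(variable: str) -> dict[str, tuple[float, float]]:
    """Published yield-vs-ratio lines, season → (slope, intercept)."""
    if variable not in _RATIO_LINES:
        raise KeyError(f"variable must be 'dma' or 'na', got {variable!r}")
    return dict(_RATIO_LINES[variable])
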