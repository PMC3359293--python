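"""Bias correction of model climate and century-scale projection.

Each climate model's monthly output is rescaled so that its reference-period
(default 1976–2000) calendar-month means match the observed station means:
for month m and variable v, factor_m = mean(observed_mv)/mean(model_mv), and
every model value of that calendar month is multiplied by its factor.  The
ratio form is applied to both precipitation and temperature by default
(an additive offset correction for temperature is available via
``temp_mode="additive"``; the ratio on °C depends on the temperature unit,
which is why the switch exists — see the methods note).  The corrected
series drive the fitted hatching-success / emergence-rate equations through
2100; ensemble means, 10-year trailing moving averages, and Pearson trend
correlations summarise the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hindcast import HindcastResult, hindcast_series
from .regression import LinearModelFit
from .types import MonthlyClimateSeries

logger = logging.getLogger(__name__)

DEFAULT_REF_YEARS = range(1976, 2001)  # inclusive 1976..2000


@dataclass(frozen=True)
class BiasFactors:
    """Per-calendar-month correction factors for one climate model."""

    model_id: str
    precip: dict[int, float]  # month → multiplicative factor
    temp: dict[int, float]    # month → factor (ratio) or offset (additive)
    temp_mode: str = "ratio"

    def __post_init__(self) -> None:
        if self.temp_mode not in ("ratio", "additive"):
            raise ValueError(f"unknown temp_mode {self.temp_mode!r}")
        for d, name in ((self.precip, "precip"), (self.temp, "temp")):
            if set(d) != set(range(1, 13)):
                raise ValueError(f"{name} factors must cover months 1..12")
            if not all(np.isfinite(v) for v in d.values()):
                raise ValueError(f"non-finite {name} bias factor")
        if any(v <= 0 for v in self.precip.values()):
            raise ValueError("precipitation bias factors must be positive")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model_id": self.model_id, "month": m, "variable": "precip_mm",
             "factor": self.precip[m]}
            for m in range(1, 13)
        ] + [
            {"model_id": self.model_id, "month": m, "variable": "temp_c",
             "factor": self.temp[m]}
            for m in range(1, 13)
        ]
        return pd.DataFrame(rows)


def bias_factors(
    observed: MonthlyClimateSeries,
    model_hist: MonthlyClimateSeries,
    ref_years: Iterable[int] = DEFAULT_REF_YEARS,
    temp_mode: str = "ratio",
    model_id: str = "model",
) -> BiasFactors:
    """Monthly observed/model mean ratios over the reference period.

    With ``temp_mode="additive"`` the temperature entry is the observed
    minus model mean offset instead of the ratio.
    """
    ref_years = list(ref_years)
    precip: dict[int, float] = {}
    temp: dict[int, float] = {}
    for m in range(1, 13):
        obs_p = observed.monthly_mean(m, ref_years, "precip_mm")
        mod_p = model_hist.monthly_mean(m, ref_years, "precip_mm")
        if mod_p == 0:
            raise ZeroDivisionError(
                f"model mean precipitation is zero in month {m}: "
                "cannot ratio-correct"
            )
        precip[m] = obs_p / mod_p
        obs_t = observed.monthly_mean(m, ref_years, "temp_c")
        mod_t = model_hist.monthly_mean(m, ref_years, "temp_c")
        if temp_mode == "ratio":
            if mod_t == 0:
                raise ZeroDivisionError(
                    f"model mean temperature is zero in month {m}: "
                    "cannot ratio-correct (use temp_mode='additive')"
                )
            temp[m] = obs_t / mod_t
        else:
            temp[m] = obs_t - mod_t
    return BiasFactors(model_id=model_id, precip=precip, temp=temp, temp_mode=temp_mode)


def apply_bias(
    model_series: MonthlyClimateSeries, factors: BiasFactors
) -> MonthlyClimateSeries:
    """Apply per-calendar-month correction to a model series.

    Multiplicative correction conserves reference-period monthly means by
    construction and preserves relative (ratio) trends.
    """
    df = model_series.to_frame()
    pf = df["month"].map(factors.precip)
    df["precip_mm"] = df["precip_mm"] * pf
    tf = df["month"].map(factors.temp)
    if factors.temp_mode == "ratio":
        df["temp_c"] = df["temp_c"] * tf
    else:
        df["temp_c"] = df["temp_c"] + tf
    return MonthlyClimateSeries(df, source=model_series.source)


def project_model(
    corrected: MonthlyClimateSeries,
    fits: tuple[LinearModelFit, LinearModelFit],
    weights: dict[int, float] | None = None,
    seasons: "Sequence[int] | range | None" = None,
) -> HindcastResult:
    """Drive the fitted equations with one bias-corrected model series."""
    return hindcast_series(corrected, fits, weights=weights, seasons=seasons)


def ensemble_mean(
    series_by_model: Mapping[str, pd.Series],
    member_ids: Iterable[str] | None = None,
) -> pd.Series:
    """Unweighted per-season mean over ensemble members.

    Members must share the season index exactly; ``member_ids`` selects a
    sub-ensemble (e.g. the ENSO-skillful subset)."""
    ids = list(series_by_model) if member_ids is None else list(member_ids)
    if not ids:
        raise ValueError("empty ensemble member list")
    missing = [i for i in ids if i not in series_by_model]
    if missing:
        raise KeyError(f"unknown ensemble members: {missing}")
    frame = pd.DataFrame({i: series_by_model[i] for i in ids})
    if frame.isna().any().any():
        raise ValueError("ensemble members do not share a common season axis")
    return frame.mean(axis=1)


def moving_average(series: pd.Series, window: int = 10) -> pd.Series:
    """Trailing moving average; the first window−1 entries are missing."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(series) < window:
        raise ValueError(f"series shorter than window ({len(series)} < {window})")
    return series.rolling(window=window, min_periods=window).mean()


def trend_correlation(series: pd.Series) -> tuple[float, float]:
    """Pearson correlation of value against season index, with two-sided
    p-value; missing values (e.g. the moving-average burn-in) are dropped."""
    clean = series.dropna()
    if len(clean) < 3:
        raise ValueError("need at least 3 non-missing points for a trend")
    y = clean.to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("zero-variance series: trend correlation undefined")
    x = np.asarray(clean.index, dtype=float)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ProjectionSeries:
    """Per-model annual projections plus ensemble summaries."""

    per_model: dict[str, pd.DataFrame]  # model → (season, annual_h, annual_r)
    ensemble_h: pd.Series
    ensemble_r: pd.Series
    subset_h: pd.Series | None
    subset_r: pd.Series | None
    smoothed_h: pd.Series
    smoothed_r: pd.Series
    window: int
    trend_h: tuple[float, float]
    trend_r: tuple[float, float]
    clamp_count: int = 0
    bias: dict[str, BiasFactors] = field(default_factory=dict)


def project_ensemble(
    models: Mapping[str, MonthlyClimateSeries],
    observed: MonthlyClimateSeries,
    fits: tuple[LinearModelFit, LinearModelFit],
    ref_years: Iterable[int] = DEFAULT_REF_YEARS,
    seasons: "Sequence[int] | range" = range(2001, 2100),
    weights: dict[int, float] | None = None,
    subset_ids: Iterable[str] | None = None,
    window: int = 10,
    temp_mode: str = "ratio",
) -> ProjectionSeries:
    """Bias-correct every model, project each, and summarise the ensemble.

    Default projection span is the 2001–02 through 2099–2100 nesting
    seasons with a 10-season trailing moving average for trend reporting.
    """
    ref_years = list(ref_years)
    per_model: dict[str, pd.DataFrame] = {}
    bias: dict[str, BiasFactors] = {}
    h_series: dict[str, pd.Series] = {}
    r_series: dict[str, pd.Series] = {}
    clamp_count = 0
    for model_id, series in models.items():
        bf = bias_factors(observed, series, ref_years, temp_mode=temp_mode,
                          model_id=model_id)
        corrected = apply_bias(series, bf)
        result = project_model(corrected, fits, weights=weights, seasons=seasons)
        annual = result.annual.set_index("season_start_year")
        per_model[model_id] = result.annual
        bias[model_id] = bf
        h_series[model_id] = annual["annual_h"]
        r_series[model_id] = annual["annual_r"]
        clamp_count += result.clamp_count

    ens_h = ensemble_mean(h_series)
    ens_r = ensemble_mean(r_series)
    subset_h = subset_r = None
    if subset_ids is not None:
        subset_h = ensemble_mean(h_series, subset_ids)
        subset_r = ensemble_mean(r_series, subset_ids)
    smoothed_h = moving_average(ens_h, window)
    smoothed_r = moving_average(ens_r, window)
    return ProjectionSeries(
        per_model=per_model,
        ensemble_h=ens_h,
        ensemble_r=ens_r,
        subset_h=subset_h,
        subset_r=subset_r,
        smoothed_h=smoothed_h,
        smoothed_r=smoothed_r,
        window=window,
        trend_h=trend_correlation(smoothed_h),
        trend_r=trend_correlation(smoothed_r),
        clamp_count=clamp_count,
        bias=bias,
    )
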