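"""Lagged climate predictors and the historical hindcast.

A nesting season opens in October of year Y and closes in February of
Y+1; clutches laid Oct–Jan incubate for about two months.  For a clutch
laid in month m of season Y the predictors are

* ``precip_prev2_mm``      — precipitation accumulated over the two full
  calendar months preceding m (Oct-laid clutches: Aug + Sep of Y);
* ``precip_oct_mm``        — October precipitation of the season (the last
  rains before the dry season sets in);
* ``temp_incubation_c``    — mean air temperature over the two incubation
  months, m and m+1;
* ``precip_sep_oct_mm``    — September + October precipitation of the season.

Months that cross the calendar-year boundary resolve within the season:
January clutches of season Y use Nov/Dec of Y and Jan/Feb of Y+1.  Applying
the fitted equations month by month and weighting by the temporal
distribution of nesting yields one annual hatching-success and one annual
emergence-rate value per season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nests import DEFAULT_LAY_WEIGHTS, weighted_annual
from .regression import LinearModelFit, QuadraticFit, predict_with_flag, quadratic_fit
from .types import LAY_MONTHS, MEISeries, MonthlyClimateSeries, shift_month

logger = logging.getLogger(__name__)

HATCH_PREDICTORS = ("precip_prev2_mm", "precip_oct_mm", "temp_incubation_c")
EMERGENCE_PREDICTORS = ("temp_incubation_c", "precip_sep_oct_mm")


@dataclass(frozen=True)
class PredictorRow:
    """Climate predictors for one (season, lay month) stratum."""

    season_start_year: int
    lay_month: int
    precip_prev2_mm: float
    precip_oct_mm: float
    temp_incubation_c: float
    precip_sep_oct_mm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "season_start_year": self.season_start_year,
            "lay_month": self.lay_month,
            "precip_prev2_mm": self.precip_prev2_mm,
            "precip_oct_mm": self.precip_oct_mm,
            "temp_incubation_c": self.temp_incubation_c,
            "precip_sep_oct_mm": self.precip_sep_oct_mm,
        }

    def get(self, key: str, default=None):
        return getattr(self, key, default)


def lay_calendar_year(season_start_year: int, lay_month: int) -> int:
    """Calendar year in which a clutch of the given lay month is laid."""
    return season_start_year if lay_month >= 10 else season_start_year + 1


def build_predictors(
    weather: MonthlyClimateSeries, season_start_year: int, lay_month: int
) -> PredictorRow:
    """Assemble the predictor row for one season × lay month.

    Raises :class:`~hatchclim.types.MissingCovariateError` (naming the
    month) if any required weather month is absent.
    """
    if lay_month not in LAY_MONTHS:
        raise ValueError(f"lay_month must be one of {LAY_MONTHS}, got {lay_month}")
    year = lay_calendar_year(season_start_year, lay_month)
    ym_prev1 = shift_month(year, lay_month, -1)
    ym_prev2 = shift_month(year, lay_month, -2)
    ym_next = shift_month(year, lay_month, +1)
    return PredictorRow(
        season_start_year=season_start_year,
        lay_month=lay_month,
        precip_prev2_mm=weather.precip(*ym_prev2) + weather.precip(*ym_prev1),
        precip_oct_mm=weather.precip(season_start_year, 10),
        temp_incubation_c=0.5 * (weather.temp(year, lay_month) + weather.temp(*ym_next)),
        precip_sep_oct_mm=(
            weather.precip(season_start_year, 9) + weather.precip(season_start_year, 10)
        ),
    )


def predictor_table(
    weather: MonthlyClimateSeries,
    seasons: "list[int] | range",
    extended: bool = False,
) -> pd.DataFrame:
    """Predictor rows for every season × lay month.

    With ``extended=True`` the alternative precipitation accumulation
    windows screened during model development are added as audit columns:
    one and three months before laying, the two incubation months, and the
    May–November rainy-season total.
    """
    rows = []
    for season in seasons:
        for month in LAY_MONTHS:
            row = build_predictors(weather, season, month).as_dict()
            if extended:
                year = lay_calendar_year(season, month)
                prev = [shift_month(year, month, -k) for k in (1, 2, 3)]
                row["precip_prev1_mm"] = weather.precip(*prev[0])
                row["precip_prev3_mm"] = sum(weather.precip(*ym) for ym in prev)
                row["precip_incubation_mm"] = weather.precip(year, month) + weather.precip(
                    *shift_month(year, month, +1)
                )
                row["precip_rainy_season_mm"] = sum(
                    weather.precip(season, m) for m in range(5, 12)
                )
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class HindcastResult:
    """Annual hindcast plus its monthly detail and clamp diagnostics."""

    annual: pd.DataFrame  # season_start_year, annual_h, annual_r
    monthly: pd.DataFrame  # predictors + predicted h/r per stratum
    clamp_count: int

    def __len__(self) -> int:
        return len(self.annual)


def hindcast_series(
    weather: MonthlyClimateSeries,
    fits: tuple[LinearModelFit, LinearModelFit],
    weights: dict[int, float] | None = None,
    seasons: "list[int] | range | None" = None,
) -> HindcastResult:
    """Predict annual hatching success and emergence rate per season.

    ``fits`` is the (hatching success, emergence rate) model pair.  If
    ``seasons`` is omitted, every season whose full predictor window the
    weather table covers is used.
    """
    hatch_fit, emerg_fit = fits
    if seasons is None:
        years = sorted({y for y, _ in weather.to_frame()[["year", "month"]].itertuples(index=False)})
        seasons = [y for y in years if _season_covered(weather, y)]
        if not seasons:
            raise ValueError("weather table covers no complete nesting season")
    weights = DEFAULT_LAY_WEIGHTS if weights is None else weights

    monthly_rows = []
    annual_rows = []
    clamp_count = 0
    for season in seasons:
        h_by_month: dict[int, float] = {}
        r_by_month: dict[int, float] = {}
        for month in LAY_MONTHS:
            row = build_predictors(weather, season, month)
            h, ch = predict_with_flag(hatch_fit, row)
            r, cr = predict_with_flag(emerg_fit, row)
            clamp_count += ch + cr
            h_by_month[month] = h
            r_by_month[month] = r
            monthly_rows.append({**row.as_dict(), "pred_h": h, "pred_r": r})
        annual_rows.append(
            {
                "season_start_year": season,
                "annual_h": weighted_annual(h_by_month, weights),
                "annual_r": weighted_annual(r_by_month, weights),
            }
        )
    if clamp_count:
        logger.info("clamped %d monthly predictions to [0, 1]", clamp_count)
    return HindcastResult(
        annual=pd.DataFrame(annual_rows),
        monthly=pd.DataFrame(monthly_rows),
        clamp_count=clamp_count,
    )


def _season_covered(weather: MonthlyClimateSeries, season: int) -> bool:
    months = [(season, m) for m in (8, 9, 10, 11, 12)] + [
        (season + 1, m) for m in (1, 2)
    ]
    return all(ym in weather for ym in months)


@dataclass(frozen=True)
class MEIRelation:
    """Quadratic relations of the annual hindcast to the Sep–Oct ENSO index,
    with the extreme seasons of each hindcast series."""

    fit_h: QuadraticFit
    fit_r: QuadraticFit
    extremes: dict[str, int]  # min_h/max_h/min_r/max_r → season_start_year


def mei_relation(hindcast: HindcastResult, mei: MEISeries) -> MEIRelation:
    annual = hindcast.annual
    seasons = list(annual["season_start_year"])
    missing = [s for s in seasons if mei.get(s) is None]
    if missing:
        raise ValueError(f"MEI series lacks seasons {missing}")
    x = np.array([mei[s] for s in seasons], dtype=float)
    h = annual["annual_h"].to_numpy(dtype=float)
    r = annual["annual_r"].to_numpy(dtype=float)
    extremes = {
        "min_h": seasons[int(np.argmin(h))],
        "max_h": seasons[int(np.argmax(h))],
        "min_r": seasons[int(np.argmin(r))],
        "max_r": seasons[int(np.argmax(r))],
    }
    return MEIRelation(
        fit_h=quadratic_fit(x, h), fit_r=quadratic_fit(x, r), extremes=extremes
    )
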