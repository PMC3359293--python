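"""Synthetic ENSO-driven data with the statistical structure the pipeline
assumes.

The generator emulates four data sources for a seasonally dry Pacific-coast
nesting beach:

* a Sep–Oct ENSO index (AR(1); positive = El Niño, negative = La Niña),
* monthly station weather with a May–Nov wet season peaking in Sep–Oct and
  a nearly rainless Dec–Apr dry season, where El Niño seasons are drier and
  warmer and La Niña seasons wetter and cooler,
* clutch excavation records whose expected hatching success and emergence
  rate follow the fitted climate equations with nest-level overdispersion,
* a multi-model climate ensemble sharing the station climatology but with
  model-specific constant biases, century-scale warming (all models) and
  drying (a configurable majority), and each model's own internal ENSO-like
  variability.

Every generator draws from ``numpy.random.default_rng`` seeded by the
config seed plus a fixed per-generator stream id, so outputs are
reproducible independently of call order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .hindcast import build_predictors
from .regression import LinearModelFit, predict_response, reference_fits
from .types import (
    LAY_MONTHS,
    MEISeries,
    MonthlyClimateSeries,
    NestRecord,
    NonStationaryError,
)

# Monthly climatology defaults (Jan..Dec) for a Guanacaste-like seasonally
# dry tropical station: rains May–Nov peaking Sep–Oct near 350–400 mm,
# dry-season months near zero; air temperature 26–29 °C, warmest in the
# late dry season (Mar–Apr).
DEFAULT_PRECIP_MM = (3.0, 2.0, 5.0, 20.0, 220.0, 270.0, 160.0, 220.0,
                     380.0, 360.0, 110.0, 15.0)
DEFAULT_TEMP_C = (26.9, 27.5, 28.3, 28.7, 28.0, 27.2, 27.1, 27.0,
                  26.6, 26.5, 26.6, 26.7)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study system.

    The defaults describe the study conditions: six monitored nesting
    seasons starting 2004; ENSO persistence 0.5 season-to-season with unit
    innovation sd; a wettest-month ENSO response of −100 mm per index unit
    (scaled down the seasonal cycle, see :func:`_precip_weights`) and
    +0.5 °C per index unit with monthly weather noise of 200 mm (wettest
    month) and 1.0 °C, giving the strong interannual rainfall variability
    the station record shows; ~34 excavated clutches per lay month of ~65
    eggs; and a model ensemble warming by ~3 °C and drying by ~30% per
    century with model biases of up to ±1.5 °C and ±30% precipitation.
    """

    seed: int = 0
    n_seasons: int = 6
    start_year: int = 2004
    enso_ar_coef: float = 0.5
    enso_sd: float = 1.0
    precip_monthly_means: tuple[float, ...] = DEFAULT_PRECIP_MM
    precip_enso_slope: float = -100.0
    precip_noise_sd: float = 200.0
    temp_monthly_means: tuple[float, ...] = DEFAULT_TEMP_C
    temp_enso_slope: float = 0.5
    temp_noise_sd: float = 1.0
    nests_per_month: int = 34
    clutch_size_mean: float = 65.0
    obs_noise_sd: float = 0.12
    model_trend_temp: float = 3.0      # °C per century
    model_trend_precip: float = -0.30  # fraction per century (negative = drying)
    model_bias_temp: tuple[float, float] = (-1.5, 1.5)      # °C offset range
    model_bias_precip: tuple[float, float] = (0.7, 1.3)     # multiplicative range

    def __post_init__(self) -> None:
        if self.n_seasons < 1 or self.nests_per_month < 1:
            raise ValueError("counts must be >= 1")
        for name in ("enso_sd", "precip_noise_sd", "temp_noise_sd", "obs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for seq, name in (
            (self.precip_monthly_means, "precip_monthly_means"),
            (self.temp_monthly_means, "temp_monthly_means"),
        ):
            if len(seq) != 12:
                raise ValueError(f"{name} needs 12 monthly values")
        if any(v < 0 for v in self.precip_monthly_means):
            raise ValueError("precipitation means must be >= 0")
        if self.clutch_size_mean < 1:
            raise ValueError("clutch_size_mean must be >= 1")

    @property
    def seasons(self) -> range:
        return range(self.start_year, self.start_year + self.n_seasons)

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    # -- key-value config file -------------------------------------------
    def to_file(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "GeneratorConfig":
        kw = dict(mapping)
        for k, v in kw.items():
            if isinstance(v, list):
                kw[k] = tuple(v)
        return cls(**kw)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def season_of(year: int, month: int) -> int:
    """Map a calendar month to the nesting season whose ENSO state forces
    it: season Y spans May Y through April Y+1, so the Sep–Oct index of
    season Y governs that season's rains and the following dry season."""
    return year if month >= 5 else year - 1


def gen_mei(config: GeneratorConfig) -> MEISeries:
    """Stationary AR(1) Sep–Oct ENSO index, one value per season."""
    phi = config.enso_ar_coef
    if abs(phi) >= 1:
        raise NonStationaryError(
            f"AR(1) coefficient must lie in (-1, 1), got {phi}"
        )
    rng = _rng(config, 1)
    n = config.n_seasons
    sd = config.enso_sd
    values = np.zeros(n)
    if sd > 0:
        marginal_sd = sd / np.sqrt(1.0 - phi**2)
        values[0] = rng.normal(0.0, marginal_sd)
        innov = rng.normal(0.0, sd, size=n - 1)
        for i in range(1, n):
            values[i] = phi * values[i - 1] + innov[i - 1]
    return MEISeries(dict(zip(config.seasons, values)))


def _precip_weights(config: GeneratorConfig) -> np.ndarray:
    """Seasonal shaping of the precipitation ENSO response and noise.

    ENSO modulates the rainy season, not the nearly rainless dry months,
    so the slope and noise scale with each month's share of the wettest
    month's climatology; ``precip_enso_slope`` is then the response of the
    wettest month in mm per index unit.
    """
    means = np.asarray(config.precip_monthly_means, dtype=float)
    peak = means.max()
    return means / peak if peak > 0 else np.zeros(12)


def gen_weather(mei: MEISeries, config: GeneratorConfig) -> MonthlyClimateSeries:
    """Monthly station weather from January of the first season's year
    through April after the last season.

    Each month's values are its climatological mean plus the ENSO response
    (the season's index applied to all of that season's months; months
    belonging to unindexed shoulder seasons get a neutral index of 0) plus
    Gaussian noise; the precipitation response and noise are shaped by the
    monthly climatology (see :func:`_precip_weights`) and precipitation is
    truncated at zero."""
    for season in config.seasons:
        if mei.get(season) is None:
            raise ValueError(f"MEI series lacks season {season}")
    rng = _rng(config, 2)
    pw = _precip_weights(config)
    rows = []
    last_year = config.start_year + config.n_seasons
    for year in range(config.start_year, last_year + 1):
        months = range(1, 13) if year < last_year else range(1, 5)
        for month in months:
            idx = mei.get(season_of(year, month), 0.0)
            w = pw[month - 1]
            p = (
                config.precip_monthly_means[month - 1]
                + config.precip_enso_slope * w * idx
                + (rng.normal(0.0, config.precip_noise_sd * w)
                   if config.precip_noise_sd * w > 0 else 0.0)
            )
            t = (
                config.temp_monthly_means[month - 1]
                + config.temp_enso_slope * idx
                + (rng.normal(0.0, config.temp_noise_sd)
                   if config.temp_noise_sd > 0 else 0.0)
            )
            rows.append(
                {"year": year, "month": month,
                 "precip_mm": max(0.0, p), "temp_c": t}
            )
    return MonthlyClimateSeries(pd.DataFrame(rows), source="synthetic-station")


def gen_nests(
    weather: MonthlyClimateSeries,
    config: GeneratorConfig,
    fits: tuple[LinearModelFit, LinearModelFit] | None = None,
) -> list[NestRecord]:
    """Excavation records whose expected clutch outcomes follow the climate
    equations.

    For each season × lay month the expected hatching success H and
    emergence rate R come from the fitted equations (defaults: the packaged
    reference fits) evaluated on that month's predictors and clamped to
    [0, 1].  Per clutch, a Gaussian nest-level jitter (sd ``obs_noise_sd``)
    perturbs each probability before binomial draws: hatched S ~
    Bin(clutch, H'), emerged ~ Bin(S, R'); unhatched, live and dead counts
    are derived so all count identities hold.  A clutch with S = 0 is kept;
    its emergence rate is undefined and flagged downstream, never zeroed.
    """
    if fits is None:
        fits = reference_fits()
    hatch_fit, emerg_fit = fits
    rng = _rng(config, 3)
    records: list[NestRecord] = []
    for season in config.seasons:
        for month in LAY_MONTHS:
            row = build_predictors(weather, season, month)
            h = predict_response(hatch_fit, row)
            r = predict_response(emerg_fit, row)
            for _ in range(config.nests_per_month):
                clutch = max(1, int(rng.poisson(config.clutch_size_mean)))
                ph = _jitter(h, config.obs_noise_sd, rng)
                shells = int(rng.binomial(clutch, ph))
                unhatched = clutch - shells
                if shells > 0:
                    pr = _jitter(r, config.obs_noise_sd, rng)
                    emerged = int(rng.binomial(shells, pr))
                    in_nest = shells - emerged
                    dead = int(rng.binomial(in_nest, 0.6)) if in_nest else 0
                    live = in_nest - dead
                else:
                    live = dead = 0
                records.append(
                    NestRecord(
                        season_start_year=season,
                        lay_month=month,
                        shells=shells,
                        unhatched=unhatched,
                        live_in_nest=live,
                        dead_in_nest=dead,
                    )
                )
    return records


def _jitter(p: float, sd: float, rng: np.random.Generator) -> float:
    if sd > 0:
        p = p + rng.normal(0.0, sd)
    return min(max(p, 0.0), 1.0)


def gen_model_ensemble(
    config: GeneratorConfig,
    n_models: int = 17,
    years: Iterable[int] = range(1976, 2101),
    n_drying: int | None = None,
) -> dict[str, MonthlyClimateSeries]:
    """A multi-model monthly climate ensemble over ``years``.

    Every model shares the station climatology but adds (i) a constant
    temperature offset and a multiplicative precipitation factor drawn from
    the configured bias ranges, (ii) linear trends active over the full
    span — warming for all models, drying for ``n_drying`` of them (default
    13/17 of the ensemble, the remainder getting a weak wetting trend) —
    and (iii) the model's own AR(1) ENSO variability plus monthly noise.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    years = sorted(years)
    if n_drying is None:
        n_drying = int(round(n_models * 13 / 17))
    n_drying = min(n_drying, n_models)
    rng = _rng(config, 4)
    y0 = years[0]
    span_seasons = range(y0 - 1, years[-1] + 1)

    dry_flags = np.zeros(n_models, dtype=bool)
    dry_flags[:n_drying] = True
    rng.shuffle(dry_flags)

    phi = config.enso_ar_coef
    if abs(phi) >= 1:
        raise NonStationaryError(
            f"AR(1) coefficient must lie in (-1, 1), got {phi}"
        )

    out: dict[str, MonthlyClimateSeries] = {}
    for i in range(n_models):
        bias_t = rng.uniform(*config.model_bias_temp)
        bias_p = rng.uniform(*config.model_bias_precip)
        trend_t = config.model_trend_temp * rng.uniform(0.5, 1.5)
        if dry_flags[i]:
            trend_p = config.model_trend_precip * rng.uniform(0.5, 1.5)
        else:
            trend_p = abs(config.model_trend_precip) * rng.uniform(0.0, 0.3)
        # model-internal ENSO-like variability
        mei = {}
        prev = 0.0
        sd = config.enso_sd
        for k, season in enumerate(span_seasons):
            if sd == 0:
                mei[season] = 0.0
                continue
            if k == 0:
                prev = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
            else:
                prev = phi * prev + rng.normal(0.0, sd)
            mei[season] = prev
        pw = _precip_weights(config)
        rows = []
        for year in years:
            for month in range(1, 13):
                frac = (year + (month - 0.5) / 12 - y0) / 100.0
                idx = mei[season_of(year, month)]
                w = pw[month - 1]
                p = (
                    config.precip_monthly_means[month - 1]
                    + config.precip_enso_slope * w * idx
                    + (rng.normal(0.0, config.precip_noise_sd * w)
                       if config.precip_noise_sd * w > 0 else 0.0)
                )
                p *= bias_p * max(0.0, 1.0 + trend_p * frac)
                t = (
                    config.temp_monthly_means[month - 1]
                    + config.temp_enso_slope * idx
                    + bias_t
                    + trend_t * frac
                    + (rng.normal(0.0, config.temp_noise_sd)
                       if config.temp_noise_sd > 0 else 0.0)
                )
                rows.append(
                    {"year": year, "month": month,
                     "precip_mm": max(0.0, p), "temp_c": t}
                )
        model_id = f"model_{i + 1:02d}"
        out[model_id] = MonthlyClimateSeries(pd.DataFrame(rows), source=model_id)
    return out


def ensemble_to_frame(models: Mapping[str, MonthlyClimateSeries]) -> pd.DataFrame:
    frames = []
    for model_id, series in models.items():
        df = series.to_frame()
        df.insert(0, "model_id", model_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def ensemble_from_frame(df: pd.DataFrame) -> dict[str, MonthlyClimateSeries]:
    return {
        str(model_id): MonthlyClimateSeries(group.drop(columns="model_id"),
                                            source=str(model_id))
        for model_id, group in df.groupby("model_id", sort=True)
    }
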