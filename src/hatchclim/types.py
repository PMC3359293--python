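"""Shared domain types and errors for the nesting-climate pipeline.

The pipeline moves monthly station/model climate, a bimonthly ENSO index,
and clutch excavation counts between stages; the light containers here give
each of those a validated in-memory form with CSV round-tripping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Lay months included in the analysis (October–January); February clutches
#: are excluded upstream for low sample size.
LAY_MONTHS: tuple[int, ...] = (10, 11, 12, 1)

MONTH_ABBR = {
    1: "Jan", 2: "Feb", 3: "Mar", 4: "Apr", 5: "May", 6: "Jun",
    7: "Jul", 8: "Aug", 9: "Sep", 10: "Oct", 11: "Nov", 12: "Dec",
}


class PipelineError(Exception):
    """Base class for pipeline-specific errors."""


class UndefinedMetricError(PipelineError):
    """A nest metric is undefined for the given counts (e.g. R with S = 0)."""


class MissingCovariateError(PipelineError, KeyError):
    """A climate value needed to build a predictor is absent.

    Carries the offending (year, month) so callers can report exactly which
    month of which season is missing.
    """

    def __init__(self, year: int, month: int, what: str = "climate value"):
        self.year = int(year)
        self.month = int(month)
        super().__init__(
            f"missing {what} for {MONTH_ABBR.get(month, month)} {year}"
        )


class NonStationaryError(PipelineError):
    """AR(1) coefficient outside (−1, 1): the index process has no
    stationary distribution."""


class CollinearityError(PipelineError):
    """Perfectly collinear candidate predictors; names the columns involved."""

    def __init__(self, columns: Iterable[str]):
        self.columns = tuple(columns)
        super().__init__(
            "perfectly collinear candidate columns: " + ", ".join(self.columns)
        )


def shift_month(year: int, month: int, delta: int) -> tuple[int, int]:
    """Return (year, month) shifted by ``delta`` calendar months."""
    idx = year * 12 + (month - 1) + delta
    return idx // 12, idx % 12 + 1


@dataclass(frozen=True)
class NestRecord:
    """One excavated clutch.

    Counts follow the excavation protocol: ``shells`` (S) empty eggshells,
    ``unhatched`` (U) undeveloped eggs, and ``live_in_nest`` (L) /
    ``dead_in_nest`` (D) hatchlings found in the nest that failed to emerge.
    """

    season_start_year: int
    lay_month: int
    shells: int
    unhatched: int
    live_in_nest: int
    dead_in_nest: int

    def __post_init__(self) -> None:
        if self.lay_month not in LAY_MONTHS:
            raise ValueError(
                f"lay_month must be one of {LAY_MONTHS} (Oct–Jan), "
                f"got {self.lay_month}"
            )
        for name in ("shells", "unhatched", "live_in_nest", "dead_in_nest"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.live_in_nest + self.dead_in_nest > self.shells:
            raise ValueError(
                "hatchlings in nest (L + D) cannot exceed hatched eggs (S): "
                f"{self.live_in_nest} + {self.dead_in_nest} > {self.shells}"
            )


class MEISeries:
    """September–October multivariate ENSO index, one value per nesting
    season keyed by the season's October calendar year."""

    def __init__(self, values: Mapping[int, float]):
        items = {int(k): float(v) for k, v in values.items()}
        if any(not np.isfinite(v) for v in items.values()):
            raise ValueError("MEI values must be finite")
        self._values = dict(sorted(items.items()))

    @property
    def seasons(self) -> list[int]:
        return list(self._values)

    def __getitem__(self, season: int) -> float:
        return self._values[season]

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MEISeries) and self._values == other._values

    def get(self, season: int, default: float | None = None) -> float | None:
        return self._values.get(season, default)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"season_start_year": list(self._values),
             "mei_sep_oct": list(self._values.values())}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MEISeries":
        return cls(dict(zip(df["season_start_year"], df["mei_sep_oct"])))

    def to_csv(self, path, header_lines: Iterable[str] = ()) -> None:
        _write_csv(self.to_frame(), path, header_lines)

    @classmethod
    def from_csv(cls, path) -> "MEISeries":
        return cls.from_frame(pd.read_csv(path, comment="#"))


class MonthlyClimateSeries:
    """Monthly precipitation (mm) and mean air temperature (°C) for one
    source — a weather station or a single climate model."""

    def __init__(self, df: pd.DataFrame, source: str = "observed"):
        required = {"year", "month", "precip_mm", "temp_c"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"climate table missing columns: {sorted(missing)}")
        df = df.loc[:, ["year", "month", "precip_mm", "temp_c"]].copy()
        df["year"] = df["year"].astype(int)
        df["month"] = df["month"].astype(int)
        if not df["month"].between(1, 12).all():
            raise ValueError("month must be in 1..12")
        if df.duplicated(["year", "month"]).any():
            raise ValueError("duplicate (year, month) rows in climate table")
        df = df.sort_values(["year", "month"], ignore_index=True)
        self.source = source
        self._df = df
        self._lookup = {
            (y, m): (p, t)
            for y, m, p, t in zip(df["year"], df["month"],
                                  df["precip_mm"], df["temp_c"])
        }

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, key: tuple[int, int]) -> bool:
        return key in self._lookup

    def precip(self, year: int, month: int) -> float:
        try:
            return self._lookup[(year, month)][0]
        except KeyError:
            raise MissingCovariateError(year, month, "precipitation") from None

    def temp(self, year: int, month: int) -> float:
        try:
            return self._lookup[(year, month)][1]
        except KeyError:
            raise MissingCovariateError(year, month, "temperature") from None

    def monthly_mean(self, month: int, years: Iterable[int], var: str) -> float:
        """Mean of ``var`` ('precip_mm' or 'temp_c') for one calendar month
        over ``years``; every requested year must be present."""
        col = 0 if var == "precip_mm" else 1
        vals = []
        for y in years:
            try:
                vals.append(self._lookup[(y, month)][col])
            except KeyError:
                raise MissingCovariateError(y, month, var) from None
        return float(np.mean(vals))

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def to_csv(self, path, header_lines: Iterable[str] = ()) -> None:
        _write_csv(self._df, path, header_lines)

    @classmethod
    def from_csv(cls, path, source: str = "observed") -> "MonthlyClimateSeries":
        return cls(pd.read_csv(path, comment="#"), source=source)


def _write_csv(df: pd.DataFrame, path, header_lines: Iterable[str] = ()) -> None:
    """Write a CSV with optional ``#``-prefixed provenance header lines."""
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
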