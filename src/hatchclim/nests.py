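"""Clutch-level reproductive metrics and cohort accounting.

At excavation a clutch yields four counts: empty shells S (eggs that
hatched), unhatched eggs U, and live/dead hatchlings L/D that failed to
leave the nest.  Two proportions summarise the clutch:

* hatching success  H = S / (S + U)
* emergence rate    R = (S − (L + D)) / S

H is undefined when the clutch has no countable eggs (S + U = 0) and R is
undefined when nothing hatched (S = 0); undefined values propagate as
missing, never as zero, so stratum means stay unbiased.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import LAY_MONTHS, NestRecord, UndefinedMetricError

logger = logging.getLogger(__name__)

#: Long-run share of clutches laid in October, November, December, January.
DEFAULT_LAY_WEIGHTS: dict[int, float] = {10: 0.13, 11: 0.27, 12: 0.35, 1: 0.25}


def hatching_success(record: NestRecord) -> float:
    """Fraction of eggs that completed development, S/(S+U)."""
    total = record.shells + record.unhatched
    if total == 0:
        raise UndefinedMetricError(
            "hatching success undefined: clutch has S + U = 0"
        )
    return record.shells / total


def emergence_rate(record: NestRecord) -> float:
    """Fraction of hatched turtles that left the nest unaided,
    (S − (L + D))/S."""
    if record.shells == 0:
        raise UndefinedMetricError("emergence rate undefined: no hatched eggs (S = 0)")
    return (record.shells - (record.live_in_nest + record.dead_in_nest)) / record.shells


def monthly_means(records: Sequence[NestRecord]) -> pd.DataFrame:
    """Mean H and mean R per (season, lay month) stratum.

    Clutches with an undefined metric are dropped from that metric's mean
    only; a stratum with no defined values gets NaN.  Returns one row per
    observed stratum with columns season_start_year, lay_month, mean_h,
    mean_r, n_records, n_h, n_r.
    """
    if not records:
        raise ValueError("no nest records supplied")
    rows: dict[tuple[int, int], dict[str, list[float]]] = {}
    for rec in records:
        key = (rec.season_start_year, rec.lay_month)
        bucket = rows.setdefault(key, {"h": [], "r": [], "n": []})
        bucket["n"].append(1.0)
        try:
            bucket["h"].append(hatching_success(rec))
        except UndefinedMetricError:
            pass
        try:
            bucket["r"].append(emergence_rate(rec))
        except UndefinedMetricError:
            pass
    month_order = {m: i for i, m in enumerate(LAY_MONTHS)}
    out = [
        {
            "season_start_year": season,
            "lay_month": month,
            # sort before averaging so the mean is exactly invariant to
            # record order (floating-point summation is not associative)
            "mean_h": float(np.mean(np.sort(b["h"]))) if b["h"] else math.nan,
            "mean_r": float(np.mean(np.sort(b["r"]))) if b["r"] else math.nan,
            "n_records": len(b["n"]),
            "n_h": len(b["h"]),
            "n_r": len(b["r"]),
        }
        for (season, month), b in sorted(
            rows.items(), key=lambda kv: (kv[0][0], month_order[kv[0][1]])
        )
    ]
    return pd.DataFrame(out)


def weighted_annual(
    monthly_values: Mapping[int, float],
    weights: Mapping[int, float] | None = None,
) -> float:
    """Weight lay-month values into an annual value using the temporal
    distribution of nesting.

    ``monthly_values`` maps lay month → value; NaN marks a missing month.
    Missing months have their weight redistributed proportionally over the
    months that remain (with a warning); if every month is missing the
    annual value is undefined.
    """
    weights = dict(DEFAULT_LAY_WEIGHTS if weights is None else weights)
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError(f"lay-month weights must sum to 1, got {sum(weights.values())}")
    present = {
        m: v for m, v in monthly_values.items()
        if m in weights and v is not None and not math.isnan(v)
    }
    if not present:
        raise UndefinedMetricError("all lay months missing: annual value undefined")
    if len(present) < len(weights):
        dropped = sorted(set(weights) - set(present))
        logger.warning(
            "missing lay months %s; renormalizing remaining weights", dropped
        )
    wsum = sum(weights[m] for m in present)
    return sum(weights[m] * v for m, v in present.items()) / wsum


# ---------------------------------------------------------------------------
# Cohort accounting

@dataclass(frozen=True)
class CohortTable:
    """Per-season census of nesting females and clutches versus the subset
    that entered the analysis."""

    table: pd.DataFrame  # season_start_year, total_turtles, turtles_represented,
    #                      total_nests, nests_analyzed

    def __post_init__(self) -> None:
        req = {"season_start_year", "total_turtles", "turtles_represented",
               "total_nests", "nests_analyzed"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        t = self.table
        if (t["nests_analyzed"] > t["total_nests"]).any():
            raise ValueError("nests_analyzed exceeds total_nests in some season")
        if (t["turtles_represented"] > t["total_turtles"]).any():
            raise ValueError("turtles_represented exceeds total_turtles in some season")

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, comment="#"))


def reference_cohorts() -> CohortTable:
    """Packaged season-by-season census for the 2004–05 … 2009–10 Playa
    Grande monitoring seasons."""
    from importlib import resources

    with resources.files("hatchclim.data").joinpath("cohort_census.csv").open() as fh:
        return CohortTable.from_csv(fh)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cohort_summary(cohorts: CohortTable) -> dict[str, int]:
    """Sum the cohort census over seasons and express analysed fractions as
    integer percentages (round half away from zero)."""
    t = cohorts.table
    totals = {
        "total_turtles": int(t["total_turtles"].sum()),
        "turtles_represented": int(t["turtles_represented"].sum()),
        "total_nests": int(t["total_nests"].sum()),
        "nests_analyzed": int(t["nests_analyzed"].sum()),
    }
    if totals["total_nests"] == 0 or totals["total_turtles"] == 0:
        raise ValueError("cohort totals are zero; percentages undefined")
    totals["percent_nests"] = _round_half_away(
        100 * totals["nests_analyzed"] / totals["total_nests"]
    )
    totals["percent_turtles"] = _round_half_away(
        100 * totals["turtles_represented"] / totals["total_turtles"]
    )
    return totals


# ---------------------------------------------------------------------------
# CSV I/O

def records_to_frame(records: Iterable[NestRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "season_start_year": r.season_start_year,
                "lay_month": r.lay_month,
                "shells": r.shells,
                "unhatched": r.unhatched,
                "live_in_nest": r.live_in_nest,
                "dead_in_nest": r.dead_in_nest,
            }
            for r in records
        ]
    )


def records_from_frame(df: pd.DataFrame) -> list[NestRecord]:
    """Parse nest records, rejecting invalid counts and out-of-window lay
    months (a clutch laid outside Oct–Jan is dropped with a warning)."""
    out: list[NestRecord] = []
    for row in df.itertuples(index=False):
        if row.lay_month not in LAY_MONTHS:
            logger.warning(
                "dropping clutch laid in month %s of season %s: outside the "
                "Oct–Jan analysis window", row.lay_month, row.season_start_year
            )
            continue
        out.append(
            NestRecord(
                season_start_year=int(row.season_start_year),
                lay_month=int(row.lay_month),
                shells=int(row.shells),
                unhatched=int(row.unhatched),
                live_in_nest=int(row.live_in_nest),
                dead_in_nest=int(row.dead_in_nest),
            )
        )
    return out


def records_from_csv(path) -> list[NestRecord]:
    return records_from_frame(pd.read_csv(path, comment="#"))
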