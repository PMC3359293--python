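"""Stepwise multiple regression, standardized coefficients, quadratic ENSO
fits, and prediction from fitted coefficients.

The monthly means of hatching success and emergence rate are modelled as
ordinary least squares linear functions of lagged climate predictors.
Predictor selection is forward stepwise with backward elimination on
partial t-test p-values (enter/remove thresholds both default to 0.05).
Standardized partial regression coefficients β_j = b_j·sd(x_j)/sd(y) rank
the retained predictors; their absolute values, normalised to percentages
with largest-remainder rounding, give each predictor's share of the
variance the model explains.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import CollinearityError

logger = logging.getLogger(__name__)


@dataclass
class LinearModelFit:
    """A fitted (or externally supplied) multiple linear regression in
    effective additive form: y = intercept + Σ_j coefficients[j]·x_j."""

    response: str
    predictor_names: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    r_squared: float = math.nan
    n: int = 0
    standardized_coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.predictor_names = tuple(self.predictor_names)
        if set(self.coefficients) != set(self.predictor_names):
            raise ValueError("one coefficient per retained predictor is required")
        if not math.isnan(self.r_squared) and not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def to_json(self) -> str:
        d = asdict(self)
        d["predictor_names"] = list(self.predictor_names)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LinearModelFit":
        d = json.loads(text)
        d["predictor_names"] = tuple(d["predictor_names"])
        return cls(**d)


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic y = intercept + linear_coef·x + quadratic_coef·x²."""

    intercept: float
    linear_coef: float
    quadratic_coef: float
    r_squared: float
    n: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.intercept + self.linear_coef * x + self.quadratic_coef * x**2


# ---------------------------------------------------------------------------
# Stepwise selection

def _check_candidates(X: pd.DataFrame) -> None:
    sds = X.std(ddof=1)
    constant = [c for c in X.columns if sds[c] == 0 or not np.isfinite(sds[c])]
    if constant:
        raise ValueError(f"constant candidate columns not allowed: {constant}")
    # flag exact linear dependence among candidates (with intercept)
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        involved = []
        for j, name in enumerate(X.columns):
            others = np.delete(arr, j + 1, axis=1)
            resid = arr[:, j + 1] - others @ np.linalg.lstsq(
                others, arr[:, j + 1], rcond=None
            )[0]
            scale = np.linalg.norm(arr[:, j + 1]) or 1.0
            if np.linalg.norm(resid) / scale < 1e-10:
                involved.append(name)
        raise CollinearityError(involved or list(X.columns))


def _ols(y: np.ndarray, X: pd.DataFrame, cols: Sequence[str]):
    design = sm.add_constant(X.loc[:, list(cols)], has_constant="add")
    return sm.OLS(y, design).fit()


def stepwise_fit(
    y: Sequence[float],
    candidates: pd.DataFrame,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
    response: str = "y",
) -> LinearModelFit:
    """Forward-selection-with-backward-elimination OLS.

    At each step the candidate with the smallest partial t-test p-value
    below ``alpha_enter`` enters; any retained predictor whose p-value
    rises above ``alpha_remove`` is dropped again.  If nothing enters, an
    intercept-only fit is returned with a warning.  Non-finite p-values
    (e.g. from an exact fit leaving zero residual variance) never trigger
    entry.
    """
    y = np.asarray(y, dtype=float)
    X = candidates.copy()
    if len(y) != len(X):
        raise ValueError("response and candidate matrix lengths differ")
    if len(y) <= X.shape[1] + 1:
        raise ValueError(
            f"need n > p + 1 observations (n={len(y)}, p={X.shape[1]})"
        )
    _check_candidates(X)

    included: list[str] = []
    while True:
        changed = False
        # forward step
        best_name, best_p = None, None
        for name in X.columns:
            if name in included:
                continue
            res = _ols(y, X, included + [name])
            p = float(res.pvalues.get(name, math.nan))
            if np.isfinite(p) and (best_p is None or p < best_p):
                best_name, best_p = name, p
        if best_name is not None and best_p < alpha_enter:
            included.append(best_name)
            changed = True
        # backward sweep
        while included:
            res = _ols(y, X, included)
            pvals = res.pvalues.drop("const")
            pvals = pvals[np.isfinite(pvals.to_numpy())]
            if len(pvals) == 0:
                break
            worst = pvals.idxmax()
            if pvals[worst] > alpha_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if not included:
        logger.warning(
            "no candidate passed alpha_enter=%.3g; returning intercept-only fit",
            alpha_enter,
        )
        mean = float(np.mean(y))
        se = float(np.std(y, ddof=1) / math.sqrt(len(y)))
        return LinearModelFit(
            response=response,
            predictor_names=(),
            intercept=mean,
            coefficients={},
            standard_errors={"intercept": se},
            p_values={},
            r_squared=0.0,
            n=len(y),
        )

    res = _ols(y, X, included)
    fit = LinearModelFit(
        response=response,
        predictor_names=tuple(included),
        intercept=float(res.params["const"]),
        coefficients={c: float(res.params[c]) for c in included},
        standard_errors={
            "intercept": float(res.bse["const"]),
            **{c: float(res.bse[c]) for c in included},
        },
        p_values={c: float(res.pvalues[c]) for c in included},
        r_squared=min(max(float(res.rsquared), 0.0), 1.0),
        n=len(y),
    )
    fit.standardized_coefficients = standardized_coefficients(fit, X, y)
    return fit


def standardized_coefficients(
    fit: LinearModelFit, X: pd.DataFrame, y: Sequence[float]
) -> dict[str, float]:
    """β_j = b_j · sd(x_j)/sd(y), sample sd (n−1 denominator)."""
    y = np.asarray(y, dtype=float)
    sy = float(np.std(y, ddof=1))
    if sy == 0:
        raise ValueError("zero-variance response: standardization undefined")
    return {
        name: fit.coefficients[name] * float(np.std(X[name].to_numpy(), ddof=1)) / sy
        for name in fit.predictor_names
    }


def variance_contributions(std_coefs: Sequence[float]) -> list[int]:
    """Integer percentage share of each standardized coefficient,
    100·|β_j|/Σ|β|, rounded by largest remainder so the shares sum to 100
    exactly."""
    mags = np.abs(np.asarray(std_coefs, dtype=float))
    total = mags.sum()
    if total == 0:
        raise ValueError("all standardized coefficients are zero")
    raw = 100.0 * mags / total
    floors = np.floor(raw).astype(int)
    remainder = int(round(100 - floors.sum()))
    # hand out the leftover points to the largest fractional parts
    order = np.argsort(-(raw - floors), kind="stable")
    shares = floors.copy()
    for idx in order[:remainder]:
        shares[idx] += 1
    return shares.tolist()


def quadratic_fit(x: Sequence[float], y: Sequence[float]) -> QuadraticFit:
    """OLS fit of y on (1, x, x²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 4:
        raise ValueError(f"need at least 4 points for a quadratic fit, got {len(x)}")
    if np.std(x) == 0:
        raise ValueError("zero-variance regressor: quadratic fit degenerate")
    design = np.column_stack([np.ones_like(x), x, x**2])
    res = sm.OLS(y, design).fit()
    return QuadraticFit(
        intercept=float(res.params[0]),
        linear_coef=float(res.params[1]),
        quadratic_coef=float(res.params[2]),
        r_squared=min(max(float(res.rsquared), 0.0), 1.0),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Prediction

def predict_response(
    fit: LinearModelFit,
    row: Mapping[str, float],
    clamp: bool = True,
) -> float:
    """Evaluate the additive linear form on one predictor row.

    Responses are proportions, so by default out-of-range values are clamped
    to [0, 1]; see :func:`predict_with_flag` when the caller needs to count
    clamping events.
    """
    return predict_with_flag(fit, row, clamp=clamp)[0]


def predict_with_flag(
    fit: LinearModelFit,
    row: Mapping[str, float],
    clamp: bool = True,
) -> tuple[float, bool]:
    """As :func:`predict_response`, returning (value, was_clamped)."""
    getter = row.get if hasattr(row, "get") else lambda k, d=None: getattr(row, k, d)
    value = fit.intercept
    for name in fit.predictor_names:
        x = getter(name)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            raise KeyError(f"predictor {name!r} missing from row")
        value += fit.coefficients[name] * float(x)
    if clamp and not 0.0 <= value <= 1.0:
        clamped = min(max(value, 0.0), 1.0)
        logger.debug(
            "prediction %.4f for %s clamped to %.1f", value, fit.response, clamped
        )
        return clamped, True
    return float(value), False


# ---------------------------------------------------------------------------
# Reference coefficients

def reference_fits() -> tuple[LinearModelFit, LinearModelFit]:
    """The packaged (hatching success, emergence rate) regression models
    estimated from the 2004–2010 Playa Grande excavation series.

    The effective additive coefficients carry their printed signs: the
    incubation-temperature effect is negative for both responses (warm
    incubations are unfavourable) and every precipitation effect positive.
    """
    text = resources.files("hatchclim.data").joinpath("reference_fits.json").read_text()
    blob = json.loads(text)
    hatch = LinearModelFit.from_json(json.dumps(blob["hatching_success"]))
    emerg = LinearModelFit.from_json(json.dumps(blob["emergence_rate"]))
    return hatch, emerg
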