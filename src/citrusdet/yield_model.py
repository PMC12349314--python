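"""Count-to-yield regression for citrus trees.

A detector counts the fruit visible in a single side view of a tree (the
"unilateral" count); the true crop load is larger because fruit hide behind
foliage and on the far side.  An ordinary-least-squares polynomial fit of
true count on detected count corrects for this: degree 1 for the green-fruit
stage, degree 2 for the ripening stage.  Model quality is reported as the
coefficient of determination R^2 = 1 - SSres/SStot, in both its plain and
its sample-size/degree-adjusted form.

Validation bookkeeping per tree: E1 = |actual - detected|,
E2 = |actual - predicted|, and the error rate E2/actual as a percentage.
Display rates are truncated (not rounded) to one decimal and their mean to
two decimals -- the arithmetic convention that reproduces the reference
tables digit for digit.

The reference count tables (10 fitting trees and 6 validation trees per
stage) ship as packaged CSV fixtures, see ``paper_tables``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["CountPair", "RegressionFit", "TreeRecord", "fit_polynomial",
           "coefficient_of_determination", "predict_count",
           "evaluate_predictions", "mean_error_rate", "paper_tables",
           "fit_stage", "truncate"]

STAGE_DEGREE = {"green": 1, "ripe": 2}


@dataclass(frozen=True)
class CountPair:
    detect: int
    actual: int

    def __post_init__(self):
        if self.detect < 0 or self.actual < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class RegressionFit:
    degree: int
    coefficients: tuple        # constant upward: (c, b[, a])
    r2_plain: float
    r2_adjusted: float
    n: int

    def __call__(self, x: float) -> float:
        return float(sum(c * x ** k for k, c in enumerate(self.coefficients)))


@dataclass
class TreeRecord:
    tree_id: int
    detect: float
    actual: float
    predicted: int
    e1: float
    e2: float
    error_rate: float          # percentage, truncated to one decimal


def truncate(x: float, decimals: int) -> float:
    """Truncate toward zero at `decimals` places (2.59 -> 2.5 at one place)."""
    f = 10.0 ** decimals
    return math.floor(x * f + 1e-9) / f


def fit_polynomial(pairs, degree: int) -> RegressionFit:
    """Ordinary least squares of actual on detect, degree 1 or 2."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    pts = [(p.detect, p.actual) if isinstance(p, CountPair) else tuple(p)
           for p in pairs]
    n = len(pts)
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} pairs, got {n}")
    x = np.array([p[0] for p in pts], float)
    y = np.array([p[1] for p in pts], float)
    if np.ptp(x) == 0:
        raise ValueError("design is rank deficient: all detect values equal")
    coef_desc = np.polyfit(x, y, degree)
    y_hat = np.polyval(coef_desc, x)
    r2 = coefficient_of_determination(y, y_hat, degree, adjusted=False)
    r2a = coefficient_of_determination(y, y_hat, degree, adjusted=True)
    return RegressionFit(degree=degree,
                         coefficients=tuple(coef_desc[::-1]),
                         r2_plain=r2, r2_adjusted=r2a, n=n)


def coefficient_of_determination(y, y_hat, n_predictors: int,
                                 adjusted: bool = False) -> float:
    """R^2 = 1 - SSres/SStot; the adjusted variant scales both sums by
    their degrees of freedom (n - p - 1 and n - 1)."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    n = len(y)
    if n < n_predictors + 2:
        raise ValueError("too few observations")
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero total sum of squares")
    if not adjusted:
        return 1.0 - ss_res / ss_tot
    p = n_predictors
    return 1.0 - (ss_res / (n - p - 1)) / (ss_tot / (n - 1))


def predict_count(fit: RegressionFit, detect: float) -> int:
    """Evaluate the fit and round half away from zero; never negative."""
    if detect < 0:
        raise ValueError("detect must be non-negative")
    v = fit(detect)
    r = math.floor(v + 0.5) if v >= 0 else -math.floor(-v + 0.5)
    return max(int(r), 0)


def evaluate_predictions(records, fit: RegressionFit = None):
    """Per-tree error table and the mean error rate.

    `records` is an iterable of (tree_id, detect, actual[, predicted]);
    when `predicted` is missing a `fit` must be given to produce it.
    Returns (list[TreeRecord], mean_rate) with display rates truncated to
    one decimal and the mean of those rates truncated to two decimals.
    """
    out = []
    for rec in records:
        rec = tuple(rec)
        tree_id, detect, actual = rec[:3]
        if actual <= 0:
            raise ValueError(f"tree {tree_id}: actual count must be positive")
        if len(rec) > 3:
            predicted = int(rec[3])
        elif fit is not None:
            predicted = predict_count(fit, detect)
        else:
            raise ValueError("predicted value or fit required")
        e1 = abs(actual - detect)
        e2 = abs(actual - predicted)
        rate = truncate(100.0 * e2 / actual, 1)
        out.append(TreeRecord(tree_id, detect, actual, predicted, e1, e2,
                              rate))
    return out, mean_error_rate([r.error_rate for r in out])


def mean_error_rate(rates) -> float:
    """Mean of per-tree percentage rates, truncated to two decimals."""
    rates = list(rates)
    if not rates:
        raise ValueError("no rates")
    return truncate(float(np.mean(rates)), 2)


def _read(name: str) -> pd.DataFrame:
    with resources.files("citrusdet").joinpath(f"data/{name}").open() as fh:
        return pd.read_csv(fh)


def paper_tables() -> dict:
    """The embedded reference count tables.

    Keys: ``green_fit`` / ``ripe_fit`` (10 fitting trees each, columns
    tree_id/detect/actual) and ``green_validation`` / ``ripe_validation``
    (6 trees each, with the printed predicted counts, E1/E2 errors and the
    printed per-tree error-rate column).
    """
    return {k: _read(f"{v}.csv") for k, v in
            [("green_fit", "green_fit"), ("ripe_fit", "ripe_fit"),
             ("green_validation", "green_validation"),
             ("ripe_validation", "ripe_validation")]}


def fit_stage(stage: str) -> RegressionFit:
    """Fit the packaged table for a stage ('green': linear, 'ripe':
    quadratic)."""
    if stage not in STAGE_DEGREE:
        raise ValueError("stage must be 'green' or 'ripe'")
    df = paper_tables()[f"{stage}_fit"]
    pairs = list(zip(df["detect"], df["actual"]))
    return fit_polynomial(pairs, STAGE_DEGREE[stage])
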