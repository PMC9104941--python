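"""Descriptive and agreement statistics for radar-vs-reference evaluation.

The agreement report quantifies how radar HR/BR estimates track a
reference series: error moments (MSE, RMSE, MAE, MedAE) over
e_i = estimate_i - reference_i, the coefficient of determination

    R^2 = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2

with y the radar estimates, yhat the reference readings and ybar the mean
of the radar estimates (the convention this evaluation suite follows; the
textbook variant centring on the reference mean is available via
``r2_convention="reference_mean"``), adjusted Fisher-Pearson skewness of
the estimates, and Tukey boxplot fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR) with
linear-interpolation quartiles for outlier counting.

Variance and SD use the sample (n-1) convention throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as spstats

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class MetricsReport:
    mean: float
    variance: float
    sd: float
    skewness: float  # NaN when undefined (zero variance)
    upper_bound: float
    lower_bound: float
    n_outliers: int
    mse: float = math.nan
    rmse: float = math.nan
    mae: float = math.nan
    medae: float = math.nan
    r_squared: float = math.nan  # NaN when undefined

    def as_dict(self) -> dict:
        return {
            k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in self.__dict__.items()
        }


def _tukey_fences(values: np.ndarray) -> tuple[float, float, int]:
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    iqr = q3 - q1
    lower = q1 - 1.5 * iqr
    upper = q3 + 1.5 * iqr
    n_out = int(np.sum((values < lower) | (values > upper)))
    return float(upper), float(lower), n_out


def _skewness(values: np.ndarray) -> float:
    scale = max(1.0, float(np.max(np.abs(values))))
    if np.std(values, ddof=1) <= 1e-12 * scale:
        return math.nan  # skewness undefined for (near-)constant data
    return float(spstats.skew(values, bias=False))


def descriptive_report(values: Sequence[float]) -> MetricsReport:
    """Mean, sample variance/SD, adjusted skewness, Tukey fences, outliers."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise InvalidArgumentError("need >= 2 values")
    upper, lower, n_out = _tukey_fences(x)
    var = float(np.var(x, ddof=1))
    return MetricsReport(
        mean=float(np.mean(x)),
        variance=var,
        sd=math.sqrt(var),
        skewness=_skewness(x),
        upper_bound=upper,
        lower_bound=lower,
        n_outliers=n_out,
    )


def agreement_report(
    estimates: Sequence[float],
    reference: Sequence[float],
    r2_convention: str = "estimate_mean",
) -> MetricsReport:
    """Full agreement report of radar estimates against a reference series."""
    y = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if len(y) != len(ref):
        raise InvalidArgumentError("estimates and reference differ in length")
    if len(y) < 2:
        raise InvalidArgumentError("need >= 2 paired values")
    e = y - ref
    mse = float(np.mean(e**2))
    if r2_convention == "estimate_mean":
        centre = float(np.mean(y))
    elif r2_convention == "reference_mean":
        centre = float(np.mean(ref))
    else:
        raise InvalidArgumentError(f"unknown r2_convention {r2_convention!r}")
    ss_tot = float(np.sum((y - centre) ** 2))
    r2 = math.nan if ss_tot == 0 else 1.0 - float(np.sum(e**2)) / ss_tot
    base = descriptive_report(y)
    return MetricsReport(
        mean=base.mean,
        variance=base.variance,
        sd=base.sd,
        skewness=base.skewness,
        upper_bound=base.upper_bound,
        lower_bound=base.lower_bound,
        n_outliers=base.n_outliers,
        mse=mse,
        rmse=math.sqrt(mse),
        mae=float(np.mean(np.abs(e))),
        medae=float(np.median(np.abs(e))),
        r_squared=r2,
    )
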