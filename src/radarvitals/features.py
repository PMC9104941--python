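"""RR-interval heart-rate-variability features for arrhythmia screening.

Five statistics over an RR-interval sequence, plus age and gender, form
the classifier's 7-dimensional feature vector:

    mean_rr        mean RR interval (s)
    norm_max_diff  (max - min) / mean                (dimensionless)
    rmssd          sqrt(sum_{i=2..n}(RR_i - RR_{i-1})^2 / (n - 2))  (s)
    cov            sample SD / mean                  (dimensionless)
    nad            sum |RR_i - mean| / (mean * n)    (dimensionless)

The RMSSD denominator n-2 (n = number of intervals) is the published
convention this toolkit follows; the textbook n-1 (one per successive
difference) is available via ``rmssd_denominator="n_minus_1"``.  With only
two intervals the published denominator vanishes and RMSSD is reported as
missing (NaN), never fabricated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

GENDER_CODES = {"male": 1, "female": 0}  # male=1, female=0


@dataclass(frozen=True)
class RRFeatureVector:
    mean_rr: float
    norm_max_diff: float
    rmssd: float
    cov: float
    nad: float
    age: float
    gender_code: int

    def to_array(self) -> np.ndarray:
        """Feature order used throughout training and prediction."""
        return np.array(
            [
                self.mean_rr,
                self.norm_max_diff,
                self.rmssd,
                self.cov,
                self.nad,
                self.age,
                self.gender_code,
            ],
            dtype=float,
        )

    @property
    def rmssd_missing(self) -> bool:
        return math.isnan(self.rmssd)


def rr_intervals(peak_times: Sequence[float]) -> np.ndarray:
    """Successive differences of >= 3 strictly increasing peak times."""
    t = np.asarray(peak_times, dtype=float)
    if len(t) < 3:
        raise InvalidArgumentError("need >= 3 peaks for RR intervals")
    d = np.diff(t)
    if np.any(d <= 0):
        raise InvalidArgumentError("peak times must be strictly increasing")
    return d


def compute_features(
    intervals: Sequence[float],
    age: float,
    gender_code: int,
    rmssd_denominator: str = "printed",
) -> RRFeatureVector:
    """Feature vector from RR intervals (seconds).

    ``rmssd_denominator``: "printed" divides the sum of squared successive
    differences by n-2; "n_minus_1" divides by the number of differences.
    """
    rr = np.asarray(intervals, dtype=float)
    n = len(rr)
    if n < 2:
        raise InvalidArgumentError("need >= 2 intervals")
    if np.any(rr <= 0):
        raise InvalidArgumentError("intervals must be positive")
    mu = float(np.mean(rr))
    diffs = np.diff(rr)
    sq = float(np.sum(diffs**2))
    if rmssd_denominator == "printed":
        rmssd = math.sqrt(sq / (n - 2)) if n > 2 else math.nan
    elif rmssd_denominator == "n_minus_1":
        rmssd = math.sqrt(sq / (n - 1))
    else:
        raise InvalidArgumentError(
            f"unknown rmssd_denominator {rmssd_denominator!r}"
        )
    return RRFeatureVector(
        mean_rr=mu,
        norm_max_diff=float((np.max(rr) - np.min(rr)) / mu),
        rmssd=rmssd,
        cov=float(np.std(rr, ddof=1) / mu),
        nad=float(np.sum(np.abs(rr - mu)) / (mu * n)),
        age=float(age),
        gender_code=int(gender_code),
    )
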