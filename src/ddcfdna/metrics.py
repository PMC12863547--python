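"""Agreement statistics: MAE, RMSE, OLS fit, Lin's concordance.

Lin's concordance correlation coefficient (CCC) measures agreement with the
identity line, penalising both scale and location shifts:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x̄ − ȳ)^2)

with population (1/n) moments. It satisfies |CCC| ≤ |r| (Pearson), with
equality iff slope 1 and intercept 0. A thresholded variant drops pairs
whose reference value is at or above a cutoff (default 10%) before
computing the CCC — used when the reference-free estimator is known to lose
accuracy at high fractions — and declares the result not-calculable when
too few pairs survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

#: minimum surviving pairs for a thresholded CCC; with three or fewer points
#: the coefficient is considered not-calculable
MIN_CCC_POINTS = 4


@dataclass
class PairedSeries:
    """Paired (reference, estimate) values, e.g. (truth, estimated fraction)."""

    x: np.ndarray
    y: np.ndarray
    labels: list | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D and the same length")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError("series contain non-finite values")


def _as_series(series, y=None) -> PairedSeries:
    if isinstance(series, PairedSeries):
        return series
    return PairedSeries(np.asarray(series, float), np.asarray(y, float))


def mae(series: PairedSeries | Sequence[float], y: Sequence[float] | None = None) -> float:
    """Mean absolute error of y against x."""
    s = _as_series(series, y)
    if len(s.x) == 0:
        raise ValueError("empty series")
    return float(np.mean(np.abs(s.y - s.x)))


def rmse(series: PairedSeries | Sequence[float], y: Sequence[float] | None = None) -> float:
    """Root mean square error of y against x."""
    s = _as_series(series, y)
    if len(s.x) == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean((s.y - s.x) ** 2)))


class OlsFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def ols_fit(series: PairedSeries | Sequence[float], y: Sequence[float] | None = None) -> OlsFit:
    """Least-squares line of y on x; r² is the squared Pearson correlation."""
    s = _as_series(series, y)
    if len(s.x) < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(s.x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(s.y) == 0:
        # flat response: zero slope, no variance explained
        return OlsFit(0.0, float(s.y[0]), 0.0)
    res = stats.linregress(s.x, s.y)
    return OlsFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


def lin_ccc(series: PairedSeries | Sequence[float], y: Sequence[float] | None = None) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    s = _as_series(series, y)
    if len(s.x) < 2:
        raise ValueError("need at least 2 points for CCC")
    x, yv = s.x, s.y
    sxy = float(np.mean((x - x.mean()) * (yv - yv.mean())))
    sx2, sy2 = float(x.var()), float(yv.var())
    dmean = float(x.mean() - yv.mean())
    denom = sx2 + sy2 + dmean**2
    if denom == 0.0:
        return 1.0  # identical constant series: perfect agreement
    return 2.0 * sxy / denom


def ccc_with_exclusion(
    series: PairedSeries | Sequence[float],
    y: Sequence[float] | None = None,
    threshold: float = 0.10,
    min_points: int = MIN_CCC_POINTS,
) -> float | None:
    """Lin's CCC after dropping pairs whose reference (x) value ≥ threshold.

    Returns None (not-calculable) when fewer than ``min_points`` pairs
    survive the exclusion.
    """
    s = _as_series(series, y)
    keep = s.x < threshold
    if int(keep.sum()) < min_points:
        return None
    return lin_ccc(PairedSeries(s.x[keep], s.y[keep]))
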