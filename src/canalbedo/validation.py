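"""Agreement between one-off spectroradiometer albedo and albedometer streams.

Each spectroradiometer observation is matched to the mean of the kept
albedometer points inside a +/- half-window around the capture instant,
then agreement is quantified by ordinary least squares with Pearson's r
(two-sided t-test p).  A Deming option is provided because both devices
carry measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
from scipy import stats

from .albedometer import AlbedoSeries
from .errors import DegenerateRegression, InsufficientPairs

__all__ = ["AlignedPair", "RegressionResult", "align", "regress", "deming"]


@dataclass(frozen=True)
class AlignedPair:
    plot_id: str
    environment: tuple[int, int] | None
    timestamp: datetime
    asd_albedo: float
    albedometer_albedo: float
    time_offset: timedelta
    n_points: int


@dataclass(frozen=True)
class RegressionResult:
    n: int
    slope: float
    intercept: float
    pearson_r: float
    p_value: float


def align(
    asd_obs: Sequence[tuple[datetime, float]],
    series: AlbedoSeries,
    half_window: timedelta = timedelta(minutes=10),
    environment: tuple[int, int] | None = None,
) -> tuple[list[AlignedPair], list[tuple[datetime, float]]]:
    """Match each (timestamp, albedo) observation to its window mean.

    Returns (pairs, unmatched).  An observation with no kept albedometer
    point within +/- half_window is reported unmatched, never an error.
    ``time_offset`` is the capture instant minus the centroid of the
    matched points.
    """
    kept_ts, kept_vals = series.kept_points()
    kept_sec = np.array([t.timestamp() for t in kept_ts])
    pairs: list[AlignedPair] = []
    unmatched: list[tuple[datetime, float]] = []
    hw = half_window.total_seconds()
    for t, a in asd_obs:
        tt = t.timestamp()
        sel = np.abs(kept_sec - tt) <= hw
        if not sel.any():
            unmatched.append((t, a))
            continue
        centroid = float(kept_sec[sel].mean())
        pairs.append(
            AlignedPair(
                plot_id=series.plot_id,
                environment=environment,
                timestamp=t,
                asd_albedo=float(a),
                albedometer_albedo=float(kept_vals[sel].mean()),
                time_offset=timedelta(seconds=tt - centroid),
                n_points=int(sel.sum()),
            )
        )
    return pairs, unmatched


def _xy(pairs) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) and isinstance(pairs[0], AlignedPair):
        x = np.array([p.asd_albedo for p in pairs])
        y = np.array([p.albedometer_albedo for p in pairs])
    else:
        arr = np.asarray(pairs, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    return x, y


def regress(pairs: Sequence) -> RegressionResult:
    """OLS slope/intercept with Pearson r and two-sided p (t, n-2 df).

    Accepts AlignedPair records or an (n, 2) array of (x, y).
    """
    x, y = _xy(pairs)
    n = len(x)
    if n < 3:
        raise InsufficientPairs(f"regression needs >= 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateRegression("zero variance in one coordinate")
    fit = stats.linregress(x, y)
    return RegressionResult(
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
    )


def deming(pairs: Sequence, variance_ratio: float = 1.0) -> RegressionResult:
    """Deming (errors-in-both-variables) regression.

    ``variance_ratio`` is the ratio of error variances var(y)/var(x);
    1.0 gives orthogonal regression.  r and p are the Pearson quantities,
    unchanged by the fitting route.
    """
    x, y = _xy(pairs)
    n = len(x)
    if n < 3:
        raise InsufficientPairs(f"regression needs >= 3 pairs, got {n}")
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxx == 0 or syy == 0:
        raise DegenerateRegression("zero variance in one coordinate")
    lam = variance_ratio
    slope = (syy - lam * sxx + np.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (2 * sxy)
    intercept = y.mean() - slope * x.mean()
    r, p = stats.pearsonr(x, y)
    return RegressionResult(n=n, slope=float(slope), intercept=float(intercept),
                            pearson_r=float(r), p_value=float(p))
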