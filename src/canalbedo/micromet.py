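"""Canopy micrometeorology: profile temperature gradients and correlations.

DeltaT is the air-temperature gradient across the canopy profile, signed
as spike height minus below-flag-leaf height (upper minus lower): a
positive DeltaT means the top of the canopy is warmer.  Infrared canopy
temperature is aligned to spike-height air temperature by
nearest-in-time pairing, and trait tables are summarised as a
pairwise-complete Pearson correlation matrix with per-cell n and
two-sided p.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .albedo_core import PeriodWindows, assign_day_period
from .errors import InsufficientPairs, NoOverlapError
from .spectral_io import CTRecord, TempRecord
from .validation import RegressionResult, regress

__all__ = [
    "DeltaTObservation",
    "CorrelationMatrix",
    "delta_t",
    "align_ct_air",
    "correlation_matrix",
]


@dataclass(frozen=True)
class DeltaTObservation:
    plot_id: str
    stage: str                       # "heading" or "flowering"
    day_period: str
    delta_t_c: float                 # T_spike - T_flag
    n_pairs: int


def _match_nearest(
    ts_a: np.ndarray, ts_b: np.ndarray, tol_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices pairing each element of a with its nearest b within tol."""
    order = np.argsort(ts_b)
    sb = ts_b[order]
    pos = np.searchsorted(sb, ts_a)
    ia, ib = [], []
    for i, p in enumerate(pos):
        best, bestd = -1, np.inf
        for q in (p - 1, p):
            if 0 <= q < len(sb):
                d = abs(sb[q] - ts_a[i])
                if d < bestd:
                    best, bestd = q, d
        if best >= 0 and bestd <= tol_s:
            ia.append(i)
            ib.append(order[best])
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def delta_t(
    spike: Sequence[TempRecord],
    flag: Sequence[TempRecord],
    stage_window: tuple[date, date],
    stage: str = "flowering",
    day_period: str | None = None,
    windows: PeriodWindows | None = None,
    tolerance: timedelta = timedelta(minutes=10),
) -> DeltaTObservation:
    """Mean T_spike - T_flag over time-matched pairs in a stage window.

    Records are paired nearest-in-time within ``tolerance`` (loggers are
    never resampled).  ``day_period`` optionally restricts pairs to one
    local-clock window.  Raises :class:`NoOverlapError` when nothing pairs.
    """
    a0, a1 = stage_window
    sp = [r for r in spike if a0 <= r.timestamp.date() <= a1]
    fl = [r for r in flag if a0 <= r.timestamp.date() <= a1]
    if day_period is not None:
        sp = [r for r in sp if assign_day_period(r.timestamp, windows) == day_period]
        fl = [r for r in fl if assign_day_period(r.timestamp, windows) == day_period]
    if not sp or not fl:
        raise NoOverlapError("no records in the stage window")
    ts_s = np.array([r.timestamp.timestamp() for r in sp])
    ts_f = np.array([r.timestamp.timestamp() for r in fl])
    ia, ib = _match_nearest(ts_s, ts_f, tolerance.total_seconds())
    if len(ia) == 0:
        raise NoOverlapError("no time-matched spike/flag pairs within tolerance")
    diffs = np.array([sp[i].temp_c - fl[j].temp_c for i, j in zip(ia, ib)])
    return DeltaTObservation(
        plot_id=sp[0].plot_id,
        stage=stage,
        day_period=day_period or "all",
        delta_t_c=float(diffs.mean()),
        n_pairs=len(diffs),
    )


def align_ct_air(
    ct: Sequence[CTRecord],
    spike: Sequence[TempRecord],
    tolerance: timedelta = timedelta(minutes=10),
) -> tuple[np.ndarray, RegressionResult]:
    """Pair infrared canopy temperature with spike-height air temperature.

    Nearest-in-time pairing within ``tolerance``; OLS of CT on air
    temperature.  Returns the (n, 2) paired array (air, ct) and the
    regression.  Raises :class:`InsufficientPairs` below 3 pairs.
    """
    ts_ct = np.array([r.timestamp.timestamp() for r in ct])
    ts_sp = np.array([r.timestamp.timestamp() for r in spike])
    ia, ib = _match_nearest(ts_ct, ts_sp, tolerance.total_seconds())
    if len(ia) < 3:
        raise InsufficientPairs(f"only {len(ia)} CT/air pairs within tolerance")
    pairs = np.array([[spike[j].temp_c, ct[i].temp_c] for i, j in zip(ia, ib)])
    return pairs, regress(pairs)


@dataclass
class CorrelationMatrix:
    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def holm(self) -> pd.DataFrame:
        """Holm-adjusted p-values over the upper triangle."""
        k = len(self.traits)
        cells = [(i, j) for i in range(k) for j in range(i + 1, k)
                 if np.isfinite(self.p.iat[i, j])]
        ps = np.array([self.p.iat[i, j] for i, j in cells])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(running, 1.0)
        out = self.p.copy()
        for (i, j), a in zip(cells, adj):
            out.iat[i, j] = a
            out.iat[j, i] = a
        return out


def correlation_matrix(table: pd.DataFrame, min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-sided p and n.

    Cells with fewer than ``min_pairs`` complete pairs, or with a constant
    column over the complete pairs, are NaN (flagged by absence).
    """
    traits = [str(c) for c in table.columns]
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    M = table.to_numpy(dtype=float)
    for i in range(k):
        r[i, i], p[i, i], n[i, i] = 1.0, 0.0, int(np.isfinite(M[:, i]).sum())
        for j in range(i + 1, k):
            ok = np.isfinite(M[:, i]) & np.isfinite(M[:, j])
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < min_pairs:
                continue
            x, y = M[ok, i], M[ok, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rr, pp = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    idx = pd.Index(traits)
    return CorrelationMatrix(
        traits,
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(n, index=idx, columns=idx),
    )
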