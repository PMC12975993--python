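"""Paired-pyranometer streams to QC'd albedo time series.

An albedometer is a pair of identical pyranometers, one up-facing
(incoming shortwave) and one down-facing (reflected shortwave); their
ratio is broadband albedo.  The ratio is unstable at low irradiance, so
records below an incoming-irradiance threshold are dropped, as are
physically impossible ratios.  Every dropped record carries exactly one
reason code so the QC is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time
from typing import Sequence

import numpy as np

from .albedo_core import PeriodWindows, assign_day_period
from .errors import NoDataInWindow
from .spectral_io import IrradiancePair

__all__ = ["AlbedoSeries", "albedo_series", "noon_mean", "diurnal_summary", "moving_average"]

#: Hard upper bound on a kept albedo ratio; values above are sensor faults.
RATIO_HARD_MAX = 1.5
#: Incoming irradiance below this is night for QC purposes.
NIGHT_W_M2 = 1.0


@dataclass
class AlbedoSeries:
    """Albedo time series with per-record QC disposition.

    ``albedo`` is NaN where a record was dropped; ``reason`` holds the
    single drop reason ('' for kept records).
    """

    plot_id: str
    timestamps: list[datetime]
    albedo: np.ndarray
    kept: np.ndarray
    reason: list[str]
    report: dict = field(default_factory=dict)

    def kept_points(self) -> tuple[list[datetime], np.ndarray]:
        ts = [t for t, k in zip(self.timestamps, self.kept) if k]
        return ts, self.albedo[self.kept]


def albedo_series(
    pairs: Sequence[IrradiancePair],
    min_incoming_w_m2: float = 20.0,
    plot_id: str = "",
) -> AlbedoSeries:
    """Compute albedo = reflected/incoming with QC.

    Reason codes: ``night`` (incoming < 1 W m^-2), ``low_irradiance``
    (incoming below the threshold), ``ratio_out_of_range`` (> 1.5).
    An all-dropped stream yields an empty (but reported) series, not an
    exception.
    """
    ts = [p.timestamp for p in pairs]
    inc = np.array([p.incoming_w_m2 for p in pairs], dtype=float)
    ref = np.array([p.reflected_w_m2 for p in pairs], dtype=float)
    n = len(pairs)
    albedo = np.full(n, np.nan)
    kept = np.zeros(n, dtype=bool)
    reasons = [""] * n
    for i in range(n):
        if inc[i] < NIGHT_W_M2:
            reasons[i] = "night"
            continue
        if inc[i] < min_incoming_w_m2:
            reasons[i] = "low_irradiance"
            continue
        a = ref[i] / inc[i]
        if a > RATIO_HARD_MAX:
            reasons[i] = "ratio_out_of_range"
            continue
        albedo[i] = a
        kept[i] = True
    counts: dict[str, int] = {}
    for r in reasons:
        if r:
            counts[r] = counts.get(r, 0) + 1
    report = {"n_input": n, "n_kept": int(kept.sum()), "dropped": counts}
    return AlbedoSeries(plot_id, ts, albedo, kept, reasons, report)


def noon_mean(
    series: AlbedoSeries,
    window: tuple[time, time] = (time(11, 0), time(13, 0)),
) -> float:
    """Mean kept albedo inside the closed-open local-clock window."""
    a, b = window
    vals = [v for t, v in zip(series.timestamps, series.albedo)
            if np.isfinite(v) and a <= t.time() < b]
    if not vals:
        raise NoDataInWindow(f"no kept albedo points in window [{a}, {b})")
    return float(np.mean(vals))


def moving_average(series: AlbedoSeries, width: int) -> np.ndarray:
    """Centred moving average over kept points (odd width; for plotting)."""
    if width % 2 != 1 or width < 1:
        raise ValueError("moving-average width must be odd and positive")
    _, vals = series.kept_points()
    if len(vals) < width:
        return vals.copy()
    kernel = np.ones(width) / width
    out = vals.astype(float).copy()
    out[width // 2: len(vals) - width // 2] = np.convolve(vals, kernel, mode="valid")
    return out


def diurnal_summary(
    series: AlbedoSeries,
    windows: PeriodWindows | None = None,
    flat_tol: float = 1e-12,
) -> dict:
    """Summarise a day's series: minimum, its time, and period means.

    Flags: ``insufficient_span`` (< 3 kept points), ``non_u_shaped``
    (minimum at either end of the kept series — e.g. a monotone sensor
    fault), ``degenerate`` (flat series).
    """
    windows = windows or PeriodWindows()
    ts, vals = series.kept_points()
    flags: list[str] = []
    if len(vals) < 3:
        return {"min_albedo": float(vals.min()) if len(vals) else float("nan"),
                "time_of_min": ts[int(np.argmin(vals))] if len(vals) else None,
                "morning_mean": float("nan"), "noon_mean": float("nan"),
                "afternoon_mean": float("nan"), "flags": ["insufficient_span"]}
    imin = int(np.argmin(vals))
    if np.ptp(vals) <= flat_tol:
        flags.append("degenerate")
    elif imin == 0 or imin == len(vals) - 1:
        flags.append("non_u_shaped")
    period_vals: dict[str, list[float]] = {"morning": [], "noon": [], "afternoon": []}
    for t, v in zip(ts, vals):
        p = assign_day_period(t, windows)
        if p in period_vals:
            period_vals[p].append(v)
    means = {f"{p}_mean": (float(np.mean(v)) if v else float("nan"))
             for p, v in period_vals.items()}
    return {"min_albedo": float(vals[imin]), "time_of_min": ts[imin], **means, "flags": flags}
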