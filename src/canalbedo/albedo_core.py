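"""Radiance captures to plot-level broadband albedo.

The processing chain mirrors standard field-spectroscopy practice:

1. subtract the dark-current capture (when present);
2. estimate panel radiance at each canopy capture instant by per-band
   linear interpolation between bracketing white-reference captures;
3. reflectance = panel_reflectance x L_canopy / L_panel per band;
4. mask the atmospheric water-absorption bands
   (1350-1420, 1800-1950, 2400-2500 nm by default);
5. broadband albedo = unweighted mean of reflectance over retained bands
   (the nadir reflectance stands in for hemispherical albedo under the
   Lambertian assumption);
6. aggregate a plot's captures (nominally four) into mean +/- SEM.

Reflectance values < 0 or > 1 are flagged, never clipped — clipping would
bias the broadband mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConfigError,
    EmptySpectrumError,
    GridMismatch,
    PanelCoverageError,
    ReflectanceQCError,
)
from .spectral_io import CaptureKind, SpectralSample, WavelengthGrid

__all__ = [
    "MaskSet",
    "DEFAULT_MASKS",
    "ReflectanceSpectrum",
    "AlbedoObservation",
    "PeriodWindows",
    "subtract_dark",
    "interpolate_panel",
    "compute_reflectance",
    "apply_water_mask",
    "broadband_albedo",
    "plot_albedo",
    "assign_day_period",
    "process_session",
]

#: Water-absorption intervals (nm, closed endpoints). The instrument grid
#: ends at 2500 nm, so the long-wave mask runs to the end of the range.
DEFAULT_MASKS: tuple[tuple[int, int], ...] = ((1350, 1420), (1800, 1950), (2400, 2500))


@dataclass(frozen=True)
class MaskSet:
    """Sorted, non-overlapping closed wavelength intervals to exclude."""

    intervals: tuple[tuple[int, int], ...] = DEFAULT_MASKS

    def __post_init__(self) -> None:
        ivs = tuple(sorted((int(a), int(b)) for a, b in self.intervals))
        for a, b in ivs:
            if a > b:
                raise ConfigError(f"mask interval [{a}, {b}] is empty")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 <= b0:
                raise ConfigError("mask intervals overlap")
        object.__setattr__(self, "intervals", ivs)

    def retained(self, grid: WavelengthGrid) -> np.ndarray:
        """Boolean retain flag per grid band (False inside any interval)."""
        wl = grid.wavelengths
        keep = np.ones(len(wl), dtype=bool)
        for a, b in self.intervals:
            if a < grid.start_nm or b > grid.stop_nm:
                raise ConfigError(f"mask interval [{a}, {b}] outside grid span")
            keep &= ~((wl >= a) & (wl <= b))
        return keep


@dataclass
class ReflectanceSpectrum:
    """Per-band reflectance with retain/validity flags and QC counts."""

    plot_id: str
    timestamp: datetime
    values: np.ndarray
    retained: np.ndarray      # False where masked out
    valid: np.ndarray         # False where panel radiance was <= 0
    qc_flags: dict = field(default_factory=dict)

    @property
    def usable(self) -> np.ndarray:
        return self.retained & self.valid


@dataclass(frozen=True)
class AlbedoObservation:
    """Plot-level broadband albedo for one day period."""

    plot_id: str
    environment: tuple[int, int] | None
    day_period: str
    albedo: float
    sem: float
    n_captures: int


def subtract_dark(sample: SpectralSample, dark: SpectralSample) -> SpectralSample:
    """Subtract the dark-current capture element-wise; kind is preserved."""
    if dark.kind is not CaptureKind.DARK:
        raise ValueError(f"dark capture expected, got kind {dark.kind.value!r}")
    if sample.values.shape != dark.values.shape:
        raise GridMismatch("sample and dark capture are on different grids")
    return SpectralSample(
        sample_id=sample.sample_id,
        plot_id=sample.plot_id,
        kind=sample.kind,
        timestamp=sample.timestamp,
        values=sample.values - dark.values,
        n_internal_avg=sample.n_internal_avg,
    )


def interpolate_panel(
    panels: Sequence[SpectralSample],
    t: datetime,
    max_gap: timedelta = timedelta(minutes=20),
) -> np.ndarray:
    """Panel radiance at instant ``t`` by per-band linear interpolation.

    Between bracketing captures the interpolation is linear in time; at a
    capture timestamp the capture is returned exactly; outside the first or
    last capture the nearest capture is returned, provided it is within
    ``max_gap`` (no extrapolation).  Raises :class:`PanelCoverageError`
    otherwise.
    """
    if not panels:
        raise PanelCoverageError("no panel captures in session")
    panels = sorted(panels, key=lambda s: s.timestamp)
    times = np.array([p.timestamp.timestamp() for p in panels])
    tt = t.timestamp()
    if tt <= times[0] or tt >= times[-1]:
        idx = int(np.argmin(np.abs(times - tt)))
        if abs(times[idx] - tt) > max_gap.total_seconds():
            raise PanelCoverageError(
                f"instant {t.isoformat()} is {abs(times[idx] - tt):.0f} s from the "
                f"nearest panel capture (max_gap {max_gap.total_seconds():.0f} s)"
            )
        return panels[idx].values.copy()
    hi = int(np.searchsorted(times, tt, side="right"))
    lo = hi - 1
    w = (tt - times[lo]) / (times[hi] - times[lo])
    return (1.0 - w) * panels[lo].values + w * panels[hi].values


def compute_reflectance(
    canopy: SpectralSample,
    panel_at_t: np.ndarray,
    panel_reflectance: float | np.ndarray = 1.0,
    max_invalid_frac: float = 0.05,
) -> ReflectanceSpectrum:
    """Per-band reflectance r = panel_reflectance x L_canopy / L_panel.

    Bands where the panel radiance is <= 0 are marked invalid.  Negative
    or >1 reflectance values are kept (flagged in ``qc_flags``), never
    clipped.  Raises :class:`ReflectanceQCError` when more than
    ``max_invalid_frac`` of the bands are invalid.
    """
    panel_at_t = np.asarray(panel_at_t, dtype=float)
    if canopy.values.shape != panel_at_t.shape:
        raise GridMismatch("canopy capture and panel spectrum are on different grids")
    valid = panel_at_t > 0
    values = np.full_like(canopy.values, np.nan)
    values[valid] = canopy.values[valid] / panel_at_t[valid]
    values = values * np.asarray(panel_reflectance, dtype=float)
    n_invalid = int((~valid).sum())
    if n_invalid > max_invalid_frac * len(valid):
        raise ReflectanceQCError(
            f"{n_invalid} of {len(valid)} bands have non-positive panel radiance "
            f"(limit {max_invalid_frac:.0%})"
        )
    qc = {
        "n_negative": int(np.sum(values[valid] < 0)),
        "n_above_one": int(np.sum(values[valid] > 1)),
        "n_invalid_panel": n_invalid,
    }
    return ReflectanceSpectrum(
        plot_id=canopy.plot_id,
        timestamp=canopy.timestamp,
        values=values,
        retained=np.ones(values.shape, dtype=bool),
        valid=valid,
        qc_flags=qc,
    )


def apply_water_mask(
    r: ReflectanceSpectrum,
    masks: MaskSet | None = None,
    grid: WavelengthGrid | None = None,
) -> ReflectanceSpectrum:
    """Clear the retained flag inside each mask interval; values untouched."""
    masks = masks or MaskSet()
    grid = grid or WavelengthGrid()
    if len(r.values) != len(grid):
        raise GridMismatch("reflectance spectrum does not match grid")
    return ReflectanceSpectrum(
        plot_id=r.plot_id,
        timestamp=r.timestamp,
        values=r.values,
        retained=r.retained & masks.retained(grid),
        valid=r.valid,
        qc_flags=dict(r.qc_flags),
    )


def broadband_albedo(r: ReflectanceSpectrum) -> float:
    """Unweighted arithmetic mean of reflectance over retained, valid bands."""
    use = r.usable
    if not use.any():
        raise EmptySpectrumError("no retained bands to average")
    return float(np.mean(r.values[use]))


def plot_albedo(
    captures: Sequence[float],
    plot_id: str,
    day_period: str,
    environment: tuple[int, int] | None = None,
) -> AlbedoObservation:
    """Aggregate one plot/period's capture albedos into mean +/- SEM.

    SEM is the sample standard deviation (ddof=1) over captures divided by
    sqrt(n); 0 when a single capture is available.
    """
    vals = np.asarray(list(captures), dtype=float)
    if vals.size == 0:
        raise EmptySpectrumError(f"no captures for plot {plot_id!r}")
    sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return AlbedoObservation(
        plot_id=plot_id,
        environment=environment,
        day_period=day_period,
        albedo=float(vals.mean()),
        sem=sem,
        n_captures=int(vals.size),
    )


@dataclass(frozen=True)
class PeriodWindows:
    """Local-clock day-period windows, closed-open [start, stop).

    Defaults: early morning 08:00-10:00, solar-noon window 11:00-13:00,
    mid-afternoon 14:00-16:00.
    """

    morning: tuple[time, time] = (time(8, 0), time(10, 0))
    noon: tuple[time, time] = (time(11, 0), time(13, 0))
    afternoon: tuple[time, time] = (time(14, 0), time(16, 0))

    def __post_init__(self) -> None:
        wins = sorted([self.morning, self.noon, self.afternoon])
        for (a0, b0), (a1, b1) in zip(wins, wins[1:]):
            if a1 < b0:
                raise ConfigError("day-period windows overlap")
        for a, b in wins:
            if not a < b:
                raise ConfigError("day-period window is empty")

    def items(self):
        return (("morning", self.morning), ("noon", self.noon), ("afternoon", self.afternoon))


def assign_day_period(t: datetime, windows: PeriodWindows | None = None) -> str:
    """Label an instant morning/noon/afternoon by local clock time."""
    windows = windows or PeriodWindows()
    local = t.time()
    for name, (a, b) in windows.items():
        if a <= local < b:
            return name
    return "other"


def process_session(
    samples: Iterable[SpectralSample],
    grid: WavelengthGrid | None = None,
    masks: MaskSet | None = None,
    windows: PeriodWindows | None = None,
    panel_reflectance: float | np.ndarray = 1.0,
    max_gap: timedelta = timedelta(minutes=20),
    environments: dict[str, tuple[int, int]] | None = None,
) -> list[AlbedoObservation]:
    """Run the full chain on one measurement session.

    Dark subtraction is applied when dark captures are present and skipped
    otherwise (the instrument class usually dark-corrects internally).
    Canopy captures are grouped by (plot, day period) and aggregated.
    """
    grid = grid or WavelengthGrid()
    masks = masks or MaskSet()
    samples = list(samples)
    darks = [s for s in samples if s.kind is CaptureKind.DARK]
    dark = None
    if darks:
        dark = darks[0]
        if len(darks) > 1:
            values = np.mean([d.values for d in darks], axis=0)
            dark = SpectralSample(darks[0].sample_id, "", CaptureKind.DARK,
                                  darks[0].timestamp, values, darks[0].n_internal_avg)
    panels = [s for s in samples if s.kind is CaptureKind.PANEL]
    if dark is not None:
        panels = [subtract_dark(p, dark) for p in panels]

    groups: dict[tuple[str, str], list[float]] = {}
    for s in samples:
        if s.kind is not CaptureKind.CANOPY:
            continue
        if dark is not None:
            s = subtract_dark(s, dark)
        panel_at_t = interpolate_panel(panels, s.timestamp, max_gap=max_gap)
        refl = compute_reflectance(s, panel_at_t, panel_reflectance=panel_reflectance)
        refl = apply_water_mask(refl, masks, grid)
        a = broadband_albedo(refl)
        period = assign_day_period(s.timestamp, windows)
        groups.setdefault((s.plot_id, period), []).append(a)

    obs = []
    for (plot_id, period), vals in groups.items():
        env = environments.get(plot_id) if environments else None
        obs.append(plot_albedo(vals, plot_id, period, environment=env))
    return obs
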