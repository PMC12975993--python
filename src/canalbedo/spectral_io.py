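"""Typed record classes and text-dialect readers/writers.

All downstream modules consume the record types defined here.  The on-disk
formats are plain delimited text (UTF-8, ``.`` decimal separator, ISO-8601
timestamps with zone offset) so that fixtures are portable and diffable:

* spectra:      ``sample_id, plot_id, kind, timestamp_iso8601, wavelength_nm, radiance``
  (long format, one row per band)
* albedometer:  ``timestamp_iso8601, incoming_w_m2, reflected_w_m2``
* temperature:  ``timestamp_iso8601, plot_id, position, temp_c``
  with position in {spike, flag, canopy_ir}
* plot metadata: ``plot_id, year, tos, genotype, replicate, row, range``

Readers never silently drop rows: each returns a :class:`ReadReport`
accounting for every input row (``n_parsed + n_excluded == n_input``).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, GridMismatch

__all__ = [
    "WavelengthGrid",
    "CaptureKind",
    "SpectralSample",
    "IrradiancePair",
    "TempPosition",
    "TempRecord",
    "CTRecord",
    "PlotMeta",
    "ReadReport",
    "read_spectra",
    "write_spectra",
    "read_albedometer",
    "write_albedometer",
    "read_temperature_log",
    "write_temperature_log",
    "read_plot_meta",
    "write_plot_meta",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """The fixed 1-nm instrument grid over the shortwave range.

    The default covers 350-2500 nm inclusive (2151 bands), the full
    shortwave range of ASD-class field spectroradiometers.  Files on any
    other grid are rejected rather than resampled, because resampling
    would silently change the broadband albedo integral.
    """

    start_nm: int = 350
    stop_nm: int = 2500
    step_nm: int = 1

    def __post_init__(self) -> None:
        if self.step_nm <= 0 or self.stop_nm <= self.start_nm:
            raise ValueError("grid must be strictly increasing")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.start_nm, self.stop_nm + 1, self.step_nm)

    def __len__(self) -> int:
        return (self.stop_nm - self.start_nm) // self.step_nm + 1


class CaptureKind(str, enum.Enum):
    CANOPY = "canopy"
    PANEL = "panel"
    DARK = "dark"


@dataclass
class SpectralSample:
    """One radiance capture (canopy, white-reference panel, or dark).

    ``values`` holds radiance in instrument units on the session grid.
    ``n_internal_avg`` records how many instrument-internal spectra were
    averaged into the capture (typically 25 for canopy, 100 for panel and
    dark captures).
    """

    sample_id: str
    plot_id: str
    kind: CaptureKind
    timestamp: datetime
    values: np.ndarray
    n_internal_avg: int = 25

    def __post_init__(self) -> None:
        self.kind = CaptureKind(self.kind)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite radiance in sample {self.sample_id!r}")
        if self.kind is CaptureKind.CANOPY and not self.plot_id:
            raise ValueError(f"canopy capture {self.sample_id!r} has empty plot_id")
        if self.n_internal_avg < 1:
            raise ValueError("n_internal_avg must be positive")


@dataclass(frozen=True)
class IrradiancePair:
    """One albedometer logger record: paired pyranometer readings in W m^-2."""

    timestamp: datetime
    incoming_w_m2: float
    reflected_w_m2: float


class TempPosition(str, enum.Enum):
    SPIKE = "spike"
    FLAG = "flag"


@dataclass(frozen=True)
class TempRecord:
    """Air-temperature logger record at one canopy height."""

    timestamp: datetime
    position: TempPosition
    temp_c: float
    plot_id: str


@dataclass(frozen=True)
class CTRecord:
    """Infrared canopy-temperature record (nominal 15-min cadence)."""

    timestamp: datetime
    temp_c: float
    plot_id: str


@dataclass(frozen=True)
class PlotMeta:
    plot_id: str
    year: int
    tos: int
    genotype: str
    replicate: str
    row: int
    range: int

    @property
    def environment(self) -> tuple[int, int]:
        return (self.year, self.tos)


@dataclass
class ReadReport:
    """Row-level accounting for one reader call."""

    n_input: int = 0
    n_parsed: int = 0
    n_excluded: int = 0
    exclusions: list[str] = field(default_factory=list)

    def exclude(self, reason: str) -> None:
        self.n_excluded += 1
        self.exclusions.append(reason)

    def check(self) -> None:
        if self.n_parsed + self.n_excluded != self.n_input:
            raise AssertionError(
                f"reader accounting broken: {self.n_parsed} parsed + "
                f"{self.n_excluded} excluded != {self.n_input} input rows"
            )


class SpectraResult(NamedTuple):
    records: list[SpectralSample]
    report: ReadReport


class StreamResult(NamedTuple):
    records: list
    report: ReadReport


_SPECTRA_COLS = ["sample_id", "plot_id", "kind", "timestamp_iso8601", "wavelength_nm", "radiance"]
_ALBEDOMETER_COLS = ["timestamp_iso8601", "incoming_w_m2", "reflected_w_m2"]
_TEMPERATURE_COLS = ["timestamp_iso8601", "plot_id", "position", "temp_c"]
_META_COLS = ["plot_id", "year", "tos", "genotype", "replicate", "row", "range"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


def read_spectra(path: Union[str, Path], grid: WavelengthGrid | None = None) -> SpectraResult:
    """Read a long-format spectra file into :class:`SpectralSample` records.

    Each capture must cover the session grid exactly (same wavelength set);
    rows are re-ordered by wavelength.  Raises :class:`GridMismatch` when a
    capture's wavelengths differ from the grid, ``ValueError`` on non-finite
    radiance, and :class:`FormatError` on an unknown capture kind.
    """
    grid = grid or WavelengthGrid()
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _SPECTRA_COLS, path)
    report = ReadReport(n_input=len(df))
    expected = grid.wavelengths
    samples: list[SpectralSample] = []
    for sample_id, g in df.groupby("sample_id", sort=False):
        kind_token = str(g["kind"].iloc[0])
        try:
            kind = CaptureKind(kind_token)
        except ValueError:
            raise FormatError(f"{path}: unknown capture kind {kind_token!r} in sample {sample_id!r}")
        g = g.sort_values("wavelength_nm")
        wl = g["wavelength_nm"].to_numpy()
        if len(wl) != len(expected) or not np.array_equal(wl, expected):
            raise GridMismatch(
                f"{path}: sample {sample_id!r} has {len(wl)} bands; grid expects {len(expected)}"
            )
        values = g["radiance"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{path}: non-finite radiance in sample {sample_id!r}")
        plot_id = g["plot_id"].iloc[0]
        plot_id = "" if pd.isna(plot_id) else str(plot_id)
        n_avg = int(g["n_internal_avg"].iloc[0]) if "n_internal_avg" in g.columns else (
            25 if kind is CaptureKind.CANOPY else 100
        )
        samples.append(
            SpectralSample(
                sample_id=str(sample_id),
                plot_id=plot_id,
                kind=kind,
                timestamp=_parse_ts(g["timestamp_iso8601"].iloc[0]),
                values=values,
                n_internal_avg=n_avg,
            )
        )
        report.n_parsed += len(g)
    report.check()
    return SpectraResult(samples, report)


def write_spectra(path: Union[str, Path], samples: Sequence[SpectralSample],
                  grid: WavelengthGrid | None = None) -> None:
    grid = grid or WavelengthGrid()
    wl = grid.wavelengths
    frames = []
    for s in samples:
        if len(s.values) != len(wl):
            raise GridMismatch(f"sample {s.sample_id!r} does not match grid")
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "plot_id": s.plot_id,
                    "kind": s.kind.value,
                    "timestamp_iso8601": s.timestamp.isoformat(),
                    "wavelength_nm": wl,
                    "radiance": s.values,
                    "n_internal_avg": s.n_internal_avg,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=_SPECTRA_COLS + ["n_internal_avg"])
    out.to_csv(path, index=False, float_format="%.17g")


def _parse_ts(token) -> datetime:
    ts = pd.Timestamp(str(token))
    return ts.to_pydatetime()


def read_albedometer(path: Union[str, Path]) -> StreamResult:
    """Read an albedometer stream; output sorted by timestamp.

    Duplicate timestamps keep the first record (with a warning); records
    with a negative irradiance are excluded and counted in the report.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _ALBEDOMETER_COLS, path)
    report = ReadReport(n_input=len(df))
    records: list[IrradiancePair] = []
    seen: set = set()
    df = df.assign(ts_parsed=pd.to_datetime(df["timestamp_iso8601"]))
    df = df.sort_values("ts_parsed", kind="stable")
    for row in df.itertuples(index=False):
        inc, ref = float(row.incoming_w_m2), float(row.reflected_w_m2)
        if not (np.isfinite(inc) and np.isfinite(ref)):
            report.exclude(f"{row.timestamp_iso8601}: non-finite irradiance")
            continue
        if inc < 0 or ref < 0:
            report.exclude(f"{row.timestamp_iso8601}: negative irradiance")
            continue
        if row.ts_parsed in seen:
            warnings.warn(f"{path}: duplicate timestamp {row.timestamp_iso8601}; keeping first")
            report.exclude(f"{row.timestamp_iso8601}: duplicate timestamp")
            continue
        seen.add(row.ts_parsed)
        records.append(IrradiancePair(row.ts_parsed.to_pydatetime(), inc, ref))
        report.n_parsed += 1
    report.check()
    return StreamResult(records, report)


def write_albedometer(path: Union[str, Path], pairs: Sequence[IrradiancePair]) -> None:
    pd.DataFrame(
        {
            "timestamp_iso8601": [p.timestamp.isoformat() for p in pairs],
            "incoming_w_m2": [p.incoming_w_m2 for p in pairs],
            "reflected_w_m2": [p.reflected_w_m2 for p in pairs],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_temperature_log(
    path: Union[str, Path],
    temp_bounds: tuple[float, float] = (-20.0, 60.0),
) -> StreamResult:
    """Read a temperature log into Temp/CT records.

    Rows with position ``spike``/``flag`` become :class:`TempRecord`; rows
    with position ``canopy_ir`` become :class:`CTRecord`.  Temperatures
    outside ``temp_bounds`` are excluded with a warning (sensor sanity
    bounds; configurable).  An empty file yields an empty list.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _TEMPERATURE_COLS, path)
    report = ReadReport(n_input=len(df))
    lo, hi = temp_bounds
    records: list[Union[TempRecord, CTRecord]] = []
    df = df.assign(ts_parsed=pd.to_datetime(df["timestamp_iso8601"]))
    df = df.sort_values("ts_parsed", kind="stable")
    for row in df.itertuples(index=False):
        t = float(row.temp_c)
        if not np.isfinite(t) or not (lo <= t <= hi):
            warnings.warn(f"{path}: temperature {t} outside sanity bounds; excluded")
            report.exclude(f"{row.timestamp_iso8601}: temp {t} outside [{lo}, {hi}]")
            continue
        pos = str(row.position)
        ts = row.ts_parsed.to_pydatetime()
        plot_id = str(row.plot_id)
        if pos == "canopy_ir":
            records.append(CTRecord(ts, t, plot_id))
        else:
            try:
                records.append(TempRecord(ts, TempPosition(pos), t, plot_id))
            except ValueError:
                raise FormatError(f"{path}: unknown position token {pos!r}")
        report.n_parsed += 1
    report.check()
    return StreamResult(records, report)


def write_temperature_log(path: Union[str, Path],
                          records: Sequence[Union[TempRecord, CTRecord]]) -> None:
    rows = []
    for r in records:
        pos = "canopy_ir" if isinstance(r, CTRecord) else r.position.value
        rows.append((r.timestamp.isoformat(), r.plot_id, pos, r.temp_c))
    pd.DataFrame(rows, columns=_TEMPERATURE_COLS[:1] + _TEMPERATURE_COLS[1:]).to_csv(
        path, index=False, float_format="%.17g")


def read_plot_meta(path: Union[str, Path]) -> list[PlotMeta]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _META_COLS, path)
    metas = [
        PlotMeta(
            plot_id=str(r.plot_id),
            year=int(r.year),
            tos=int(r.tos),
            genotype=str(r.genotype),
            replicate=str(r.replicate),
            row=int(r.row),
            range=int(r.range),
        )
        for r in df.itertuples(index=False)
    ]
    seen = set()
    for m in metas:
        key = (m.environment, m.replicate, m.genotype)
        if key in seen:
            raise FormatError(f"{path}: duplicate (environment, replicate, genotype) {key}")
        seen.add(key)
    return metas


def write_plot_meta(path: Union[str, Path], metas: Sequence[PlotMeta]) -> None:
    pd.DataFrame(
        [(m.plot_id, m.year, m.tos, m.genotype, m.replicate, m.row, m.range) for m in metas],
        columns=_META_COLS,
    ).to_csv(path, index=False)
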