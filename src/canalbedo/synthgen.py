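"""Seeded generator of all fixture data, with ground truth kept beside it.

The generator emulates the structure of a wheat albedo-phenotyping
campaign: spectroradiometer sessions (canopy/panel/dark captures on the
350-2500 nm grid), 24-h paired-pyranometer streams with a U-shaped
diurnal albedo whose minimum sits at solar noon, randomised complete
block trials with known genotypic/residual variance components and GxE,
and canopy temperature-profile loggers whose plot-level gradient is
coupled to albedo at a configured correlation.

Every public generator returns ``(data, truth)`` where ``truth`` holds
the exact simulation parameters realised, so recovery tests never
re-derive truth from the data.  All randomness flows from one seed via
named substreams, so adding a fixture never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .albedo_core import MaskSet
from .spectral_io import (
    CaptureKind,
    CTRecord,
    IrradiancePair,
    PlotMeta,
    SpectralSample,
    TempPosition,
    TempRecord,
    WavelengthGrid,
)

__all__ = [
    "SynthConfig",
    "substream",
    "gen_endmembers",
    "gen_plot_spectra",
    "gen_albedometer_day",
    "gen_trial",
    "gen_rcbd",
    "gen_temperature_profiles",
    "make_plot_metas",
]

#: Default trial environments: (year, time of sowing) — two sowings in the
#: first year, the optimal sowing repeated in the second year.
DEFAULT_ENVIRONMENTS: tuple[tuple[int, int], ...] = ((2018, 1), (2018, 2), (2019, 1))

#: Deterministic environment mean offsets on the albedo scale (optimal
#: sowing slightly brighter canopies than late sowing, as in warm trials).
ENV_OFFSETS: dict[tuple[int, int], float] = {(2018, 1): 0.015, (2018, 2): -0.02, (2019, 1): 0.0}


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic campaign.

    Variance components default to the values that put line-mean H^2 at
    0.86 with three replicates; noon albedo and its diurnal curvature are
    chosen so daytime albedo stays in the 0.15-0.25 range typical of
    cereal canopies.
    """

    seed: int = 0
    n_genotypes: int = 30
    n_reps: int = 3
    environments: tuple[tuple[int, int], ...] = DEFAULT_ENVIRONMENTS
    sigma2_g: float = 0.0043
    sigma2_e: float = 0.0021
    sigma2_gxe: float = 0.001
    sigma2_block: float = 0.0005
    grand_mean: float = 0.20
    # diurnal model
    solar_noon_hour: float = 12.05        # 12:03 local
    day_length_h: float = 12.0
    max_elevation_deg: float = 60.0
    peak_irradiance_w_m2: float = 1000.0
    noon_albedo: float = 0.20
    curvature: float = 0.03               # albedo rise per unit of (sec z - sec z_noon)
    # device noise
    spectral_noise: float = 0.01          # per-capture multiplicative (log-normal)
    band_noise: float = 0.0               # per-band multiplicative (log-normal)
    pyranometer_noise_w_m2: float = 2.0
    logger_noise_c: float = 0.2
    # couplings
    rho_albedo_deltat: float = 0.48
    rho_ct_air: float = 0.99
    panel_reflectance: float = 0.99
    dark_offset: float = 5.0              # instrument dark current, radiance units

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_e", "sigma2_gxe", "sigma2_block"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho_albedo_deltat", "rho_ct_air"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must be in [-1, 1]")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# spectra

def _gauss(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / width) ** 2)


def gen_endmembers(grid: WavelengthGrid | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic vegetation and soil reflectance endmembers in [0, 1].

    The vegetation spectrum has the canonical green-peak / red-edge / NIR
    plateau shape with attenuated dips inside the water-absorption
    intervals; the soil spectrum increases monotonically with wavelength.
    """
    grid = grid or WavelengthGrid()
    wl = grid.wavelengths.astype(float)
    veg = 0.04 + 0.06 * _gauss(wl, 550, 35)
    plateau = 0.46 / (1.0 + np.exp(-(wl - 715) / 15.0))   # red-edge rise 680-750
    decline = 1.0 / (1.0 + np.exp((wl - 1650) / 350.0))   # SWIR roll-off
    veg = veg + plateau * (0.35 + 0.65 * decline)
    veg -= 0.22 * _gauss(wl, 1400, 45) + 0.28 * _gauss(wl, 1900, 60) + 0.18 * _gauss(wl, 2450, 60)
    veg = np.clip(veg, 0.01, 0.95)
    soil = 0.08 + 0.00012 * (wl - wl[0])
    soil = np.clip(soil, 0.0, 1.0)
    return veg, soil


def _mixture_spectrum(true_albedo: float, grid: WavelengthGrid,
                      veg_fraction: float = 0.8) -> np.ndarray:
    """Vegetation/soil mixture rescaled so its masked-band mean is the target."""
    veg, soil = gen_endmembers(grid)
    mix = veg_fraction * veg + (1.0 - veg_fraction) * soil
    keep = MaskSet().retained(grid)
    return mix * (true_albedo / mix[keep].mean())


def gen_plot_spectra(
    config: SynthConfig,
    true_albedo: float,
    t0: datetime,
    plot_id: str = "P001",
    n_captures: int = 4,
    irradiance_drift_per_min: float = 0.0,
    grid: WavelengthGrid | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[SpectralSample], dict]:
    """One plot's measurement session: canopy, panel and dark captures.

    Canopy radiance is irradiance times a vegetation/soil mixture scaled
    so its masked-band mean equals ``true_albedo``; panel radiance is
    irradiance times the panel reflectance; dark captures carry only the
    dark-current offset (added to every capture).  Irradiance may drift
    linearly between the two bracketing panel captures — linear panel
    interpolation then recovers it exactly.  With all noise at zero the
    processing chain inverts the construction to machine precision.
    """
    if not (0.0 < true_albedo < 1.0):
        raise ValueError("true_albedo must be in (0, 1)")
    grid = grid or WavelengthGrid()
    rng = rng or substream(config.seed, f"spectra/{plot_id}")
    mix = _mixture_spectrum(true_albedo, grid)
    panel_times = [t0 - timedelta(minutes=5), t0 + timedelta(minutes=10)]
    base_e = 1000.0

    def irradiance(t: datetime) -> float:
        dt_min = (t - panel_times[0]).total_seconds() / 60.0
        return base_e * (1.0 + irradiance_drift_per_min * dt_min)

    samples: list[SpectralSample] = []
    samples.append(
        SpectralSample(f"{plot_id}-dark", "", CaptureKind.DARK, t0 - timedelta(minutes=6),
                       np.full(len(grid), config.dark_offset), 100)
    )
    for i, tp in enumerate(panel_times):
        samples.append(
            SpectralSample(f"{plot_id}-panel{i}", "", CaptureKind.PANEL, tp,
                           irradiance(tp) * config.panel_reflectance * np.ones(len(grid))
                           + config.dark_offset, 100)
        )
    s2 = config.spectral_noise**2
    b2 = config.band_noise**2
    capture_factors = []
    for i in range(n_captures):
        tc = t0 + timedelta(seconds=40 * i)
        factor = float(np.exp(config.spectral_noise * rng.standard_normal() - s2 / 2))
        band = np.exp(config.band_noise * rng.standard_normal(len(grid)) - b2 / 2)
        capture_factors.append(factor)
        samples.append(
            SpectralSample(f"{plot_id}-c{i}", plot_id, CaptureKind.CANOPY, tc,
                           irradiance(tc) * mix * factor * band + config.dark_offset, 25)
        )
    capture_sd = float(true_albedo * np.sqrt(np.exp(s2) - 1.0))
    truth = {
        "true_albedo": float(true_albedo),
        "capture_albedo_sd": capture_sd,
        "sem": capture_sd / np.sqrt(n_captures),
        "capture_factors": capture_factors,
        "panel_reflectance": config.panel_reflectance,
    }
    return samples, truth


# ---------------------------------------------------------------------------
# albedometer streams

def _solar_geometry(config: SynthConfig, hours: np.ndarray):
    sunrise = config.solar_noon_hour - config.day_length_h / 2
    phase = (hours - sunrise) / config.day_length_h
    elev = np.where((phase > 0) & (phase < 1),
                    np.radians(config.max_elevation_deg) * np.sin(np.pi * phase), 0.0)
    return elev


def diurnal_albedo(config: SynthConfig, hours: np.ndarray) -> np.ndarray:
    """True albedo curve: minimum ``noon_albedo`` exactly at solar noon."""
    elev = _solar_geometry(config, hours)
    sec_z = np.where(elev > 0, 1.0 / np.maximum(np.cos(np.pi / 2 - elev), 1e-6), np.inf)
    sec_noon = 1.0 / np.cos(np.pi / 2 - np.radians(config.max_elevation_deg))
    with np.errstate(invalid="ignore"):
        a = config.noon_albedo + config.curvature * (sec_z - sec_noon)
    return np.clip(np.where(np.isfinite(a), a, 0.95), 0.0, 0.95)


def gen_albedometer_day(
    config: SynthConfig,
    day: date = date(2018, 10, 1),
    plot_id: str = "P001",
    cadence_min: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[IrradiancePair], dict]:
    """A 24-h paired-pyranometer stream at 1-min cadence.

    Incoming irradiance follows the solar-elevation curve (0 at night);
    reflected = albedo(t) x incoming + additive pyranometer noise.
    """
    rng = rng or substream(config.seed, f"albedometer/{plot_id}/{day.isoformat()}")
    n = int(round(24 * 60 / cadence_min))
    hours = np.arange(n) * cadence_min / 60.0
    elev = _solar_geometry(config, hours)
    incoming = config.peak_irradiance_w_m2 * np.sin(elev) / np.sin(
        np.radians(config.max_elevation_deg))
    incoming = np.maximum(incoming, 0.0)
    albedo = diurnal_albedo(config, hours)
    reflected = albedo * incoming + config.pyranometer_noise_w_m2 * rng.standard_normal(n)
    reflected = np.where(incoming > 0, np.maximum(reflected, 0.0), 0.0)
    t0 = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    pairs = [
        IrradiancePair(t0 + timedelta(hours=float(h)), float(i), float(r))
        for h, i, r in zip(hours, incoming, reflected)
    ]
    noon_idx = int(np.argmin(np.abs(hours - config.solar_noon_hour)))
    truth = {
        "alpha_noon": config.noon_albedo,
        "solar_noon": t0 + timedelta(hours=config.solar_noon_hour),
        "solar_noon_index": noon_idx,
        "true_albedo": albedo,
        "incoming": incoming,
        "n_daylight_ge_20": int(np.sum(incoming >= 20.0)),
    }
    return pairs, truth


# ---------------------------------------------------------------------------
# trials

def gen_rcbd(
    config: SynthConfig,
    environment: tuple[int, int] = (2018, 1),
    trait: str = "albedo_noon",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One balanced RCBD environment with known variance components."""
    rng = rng or substream(config.seed, f"rcbd/{environment}")
    g, r = config.n_genotypes, config.n_reps
    geno_eff = rng.normal(0.0, np.sqrt(config.sigma2_g), g)
    block_eff = rng.normal(0.0, np.sqrt(config.sigma2_block), r)
    resid = rng.normal(0.0, np.sqrt(config.sigma2_e), (g, r))
    mu = config.grand_mean + ENV_OFFSETS.get(environment, 0.0)
    y = mu + geno_eff[:, None] + block_eff[None, :] + resid
    df = pd.DataFrame(
        {
            "year": environment[0],
            "tos": environment[1],
            "genotype": np.repeat([f"G{i+1:02d}" for i in range(g)], r),
            "replicate": np.tile([f"R{j+1}" for j in range(r)], g),
            "trait_name": trait,
            "value": y.ravel(),
        }
    )
    truth = {"mu": mu, "genotype_effects": geno_eff, "block_effects": block_eff,
             "sigma2_g": config.sigma2_g, "sigma2_e": config.sigma2_e}
    return df, truth


def gen_trial(
    config: SynthConfig,
    trait: str = "albedo_noon",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Multi-environment trial: y = mu + env + g + gxe + block(env) + e.

    Environment main effects are fixed offsets; genotype, GxE, block and
    residual effects are seeded normal draws at the configured variances.
    """
    rng = rng or substream(config.seed, f"trial/{trait}")
    g, r = config.n_genotypes, config.n_reps
    envs = list(config.environments)
    geno_eff = rng.normal(0.0, np.sqrt(config.sigma2_g), g)
    gxe_eff = rng.normal(0.0, np.sqrt(config.sigma2_gxe), (g, len(envs)))
    rows = []
    for k, env in enumerate(envs):
        block_eff = rng.normal(0.0, np.sqrt(config.sigma2_block), r)
        resid = rng.normal(0.0, np.sqrt(config.sigma2_e), (g, r))
        mu = config.grand_mean + ENV_OFFSETS.get(env, 0.0)
        for i in range(g):
            for j in range(r):
                rows.append(
                    (env[0], env[1], f"G{i+1:02d}", f"R{j+1}", trait,
                     mu + geno_eff[i] + gxe_eff[i, k] + block_eff[j] + resid[i, j])
                )
    df = pd.DataFrame(rows, columns=["year", "tos", "genotype", "replicate",
                                     "trait_name", "value"])
    truth = {"genotype_effects": geno_eff, "gxe_effects": gxe_eff,
             "environments": envs, "sigma2_g": config.sigma2_g,
             "sigma2_gxe": config.sigma2_gxe, "sigma2_e": config.sigma2_e}
    return df, truth


def make_plot_metas(config: SynthConfig) -> list[PlotMeta]:
    """Deterministic plot layout for the configured trial."""
    metas = []
    for e, env in enumerate(config.environments):
        for j in range(config.n_reps):
            for i in range(config.n_genotypes):
                metas.append(
                    PlotMeta(
                        plot_id=f"E{e+1}R{j+1}G{i+1:02d}",
                        year=env[0],
                        tos=env[1],
                        genotype=f"G{i+1:02d}",
                        replicate=f"R{j+1}",
                        row=i + 1,
                        range=j + 1,
                    )
                )
    return metas


# ---------------------------------------------------------------------------
# temperature profiles

def gen_temperature_profiles(
    config: SynthConfig,
    albedo_by_plot: Mapping[str, float],
    start: date = date(2018, 9, 25),
    n_days: int = 5,
    cadence_min: float = 15.0,
    delta_t_mean: float = 1.5,
    delta_t_sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[list[TempRecord], list[CTRecord], dict]:
    """Two-height air-temperature loggers plus infrared canopy temperature.

    Each plot receives a constant profile gradient DeltaT = spike - flag
    drawn so that the across-plot correlation with albedo equals
    ``rho_albedo_deltat``; canopy temperature tracks spike-height air
    temperature with noise calibrated so their within-plot correlation is
    ``rho_ct_air``.
    """
    rng = rng or substream(config.seed, "temperature")
    plots = sorted(albedo_by_plot)
    alb = np.array([albedo_by_plot[p] for p in plots], dtype=float)
    sd = alb.std()
    z = (alb - alb.mean()) / sd if sd > 0 else np.zeros_like(alb)
    rho = config.rho_albedo_deltat
    dt_plot = delta_t_mean + delta_t_sd * (
        rho * z + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(len(plots)))

    n = int(round(n_days * 24 * 60 / cadence_min))
    hours = np.arange(n) * cadence_min / 60.0
    base = 22.0 + 7.0 * np.sin(2 * np.pi * (hours % 24 - 9.0) / 24.0)
    sig_t2 = float(base.var())
    rho_ct = config.rho_ct_air
    sig_l2 = config.logger_noise_c**2
    var_ct = sig_t2**2 / (rho_ct**2 * (sig_t2 + sig_l2)) - sig_t2
    sigma_ct = float(np.sqrt(max(var_ct, 1e-12)))

    t0 = datetime(start.year, start.month, start.day, tzinfo=timezone.utc)
    times = [t0 + timedelta(hours=float(h)) for h in hours]
    temp_records: list[TempRecord] = []
    ct_records: list[CTRecord] = []
    for p, dt_i in zip(plots, dt_plot):
        noise_f = config.logger_noise_c * rng.standard_normal(n)
        noise_s = config.logger_noise_c * rng.standard_normal(n)
        spike_true = base + dt_i
        flag = base + noise_f
        spike = spike_true + noise_s
        ct = spike_true - 1.0 + sigma_ct * rng.standard_normal(n)  # slight canopy cooling
        for t, tf, tsv, tc in zip(times, flag, spike, ct):
            temp_records.append(TempRecord(t, TempPosition.FLAG, float(tf), p))
            temp_records.append(TempRecord(t, TempPosition.SPIKE, float(tsv), p))
            ct_records.append(CTRecord(t, float(tc), p))
    truth = {
        "delta_t_by_plot": dict(zip(plots, dt_plot)),
        "rho_albedo_deltat": rho,
        "rho_ct_air": rho_ct,
        "sigma_ct": sigma_ct,
        "ct_offset": -1.0,
    }
    return temp_records, ct_records, truth
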