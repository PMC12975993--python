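"""Radiance-to-albedo chain: dark, panel interpolation, mask, averaging."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from canalbedo import albedo_core as core
from canalbedo.errors import (
    ConfigError,
    EmptySpectrumError,
    PanelCoverageError,
    ReflectanceQCError,
)
from canalbedo.spectral_io import CaptureKind, SpectralSample, WavelengthGrid

T0 = datetime(2018, 10, 1, 12, 0, tzinfo=timezone.utc)


def _sample(values, kind=CaptureKind.CANOPY, t=T0, plot="P1"):
    return SpectralSample("s", plot if kind is CaptureKind.CANOPY else "",
                          kind, t, np.asarray(values, dtype=float))


def _refl(values, grid):
    return core.ReflectanceSpectrum("P1", T0, np.asarray(values, float),
                                    np.ones(len(grid), bool), np.ones(len(grid), bool))


class TestSubtractDark:
    def test_zero_dark_is_identity(self, grid, rng):
        v = rng.uniform(0, 100, len(grid))
        out = core.subtract_dark(_sample(v), _sample(np.zeros(len(grid)), CaptureKind.DARK))
        np.testing.assert_array_equal(out.values, v)
        assert out.kind is CaptureKind.CANOPY

    def test_self_dark_is_zero(self, grid, rng):
        v = rng.uniform(0, 100, len(grid))
        out = core.subtract_dark(_sample(v), _sample(v, CaptureKind.DARK))
        np.testing.assert_array_equal(out.values, np.zeros(len(grid)))

    def test_elementwise_oracle(self, grid, rng):
        v, d = rng.uniform(0, 100, len(grid)), rng.uniform(0, 5, len(grid))
        out = core.subtract_dark(_sample(v), _sample(d, CaptureKind.DARK))
        np.testing.assert_array_equal(out.values, v - d)


class TestInterpolatePanel:
    def _panels(self, grid, vals_and_minutes):
        return [_sample(np.full(len(grid), v), CaptureKind.PANEL,
                        T0 + timedelta(minutes=m)) for v, m in vals_and_minutes]

    def test_at_knot_returns_capture(self, grid):
        panels = self._panels(grid, [(10.0, 0), (20.0, 15)])
        out = core.interpolate_panel(panels, T0)
        np.testing.assert_array_equal(out, np.full(len(grid), 10.0))

    def test_midpoint(self, grid):
        panels = self._panels(grid, [(10.0, 0), (20.0, 15)])
        out = core.interpolate_panel(panels, T0 + timedelta(minutes=7.5))
        np.testing.assert_allclose(out, 15.0)

    def test_linear_weight_oracle(self, grid, rng):
        p1, p2 = rng.uniform(1, 100, len(grid)), rng.uniform(1, 100, len(grid))
        panels = [_sample(p1, CaptureKind.PANEL, T0),
                  _sample(p2, CaptureKind.PANEL, T0 + timedelta(minutes=15))]
        t = T0 + timedelta(minutes=4.2)
        w = 4.2 / 15.0
        np.testing.assert_allclose(core.interpolate_panel(panels, t), (1 - w) * p1 + w * p2)

    def test_nearest_within_gap_no_extrapolation(self, grid):
        panels = self._panels(grid, [(10.0, 0)])
        out = core.interpolate_panel(panels, T0 + timedelta(minutes=15))
        np.testing.assert_array_equal(out, np.full(len(grid), 10.0))
        with pytest.raises(PanelCoverageError):
            core.interpolate_panel(panels, T0 + timedelta(minutes=30))


class TestReflectance:
    def test_canopy_equals_panel(self, grid, rng):
        panel = rng.uniform(10, 100, len(grid))
        r = core.compute_reflectance(_sample(panel), panel)
        np.testing.assert_allclose(r.values, 1.0)

    def test_ratio(self, grid, rng):
        panel = rng.uniform(10, 100, len(grid))
        r = core.compute_reflectance(_sample(0.2 * panel), panel)
        np.testing.assert_allclose(r.values, 0.2)

    def test_calibration_factor_passthrough(self, grid, rng):
        panel = rng.uniform(10, 100, len(grid))
        r = core.compute_reflectance(_sample(panel), panel, panel_reflectance=0.99)
        np.testing.assert_allclose(r.values, 0.99)

    def test_negative_flagged_not_clipped(self, grid, rng):
        panel = rng.uniform(10, 100, len(grid))
        canopy = 0.2 * panel
        canopy[:5] = -1.0
        r = core.compute_reflectance(_sample(canopy), panel)
        assert r.qc_flags["n_negative"] == 5
        assert (r.values[:5] < 0).all()

    def test_too_many_invalid_bands(self, grid, rng):
        panel = rng.uniform(10, 100, len(grid))
        panel[: len(grid) // 2] = 0.0
        with pytest.raises(ReflectanceQCError):
            core.compute_reflectance(_sample(np.ones(len(grid))), panel)


class TestWaterMask:
    def test_default_mask_retains_1828(self, grid):
        r = core.apply_water_mask(_refl(np.ones(len(grid)), grid))
        assert int(r.retained.sum()) == 1828

    def test_empty_mask_retains_all(self, grid):
        r = core.apply_water_mask(_refl(np.ones(len(grid)), grid), core.MaskSet(()))
        assert int(r.retained.sum()) == 2151

    def test_full_mask_retains_none(self, grid):
        r = core.apply_water_mask(_refl(np.ones(len(grid)), grid),
                                  core.MaskSet(((350, 2500),)))
        assert int(r.retained.sum()) == 0

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ConfigError):
            core.MaskSet(((1350, 1420), (1400, 1500)))

    def test_values_untouched(self, grid, rng):
        vals = rng.uniform(0, 1, len(grid))
        r = core.apply_water_mask(_refl(vals, grid))
        np.testing.assert_array_equal(r.values, vals)


class TestBroadbandAlbedo:
    def test_flat(self, grid):
        r = core.apply_water_mask(_refl(np.full(len(grid), 0.2), grid))
        assert core.broadband_albedo(r) == pytest.approx(0.2)

    def test_two_level_symmetry(self, grid):
        r = core.apply_water_mask(_refl(np.ones(len(grid)), grid))
        vals = r.values.copy()
        idx = np.flatnonzero(r.retained)
        vals[idx[: len(idx) // 2]] = 0.1
        vals[idx[len(idx) // 2:]] = 0.3
        r.values = vals
        assert core.broadband_albedo(r) == pytest.approx(0.2)

    def test_linear_reflectance_brute_force(self, grid):
        wl = grid.wavelengths
        vals = 1e-4 * (wl - 350)  # linear in wavelength
        r = core.apply_water_mask(_refl(vals, grid))
        # independent oracle: explicit summation over the retained wavelengths
        masked = set()
        for a, b in core.DEFAULT_MASKS:
            masked.update(range(a, b + 1))
        kept = [w for w in range(350, 2501) if w not in masked]
        expected = sum(1e-4 * (w - 350) for w in kept) / len(kept)
        assert core.broadband_albedo(r) == pytest.approx(expected, abs=1e-12)

    def test_empty_spectrum(self, grid):
        r = core.apply_water_mask(_refl(np.ones(len(grid)), grid),
                                  core.MaskSet(((350, 2500),)))
        with pytest.raises(EmptySpectrumError):
            core.broadband_albedo(r)

    @given(k=st.floats(0.1, 10.0))
    def test_scaling_canopy_scales_albedo(self, grid, k):
        """Scaling canopy radiance by k scales albedo by k (panel fixed)."""
        panel = np.linspace(10, 100, len(grid))
        base = core.apply_water_mask(core.compute_reflectance(_sample(0.2 * panel), panel))
        scaled = core.apply_water_mask(
            core.compute_reflectance(_sample(k * 0.2 * panel), panel))
        assert core.broadband_albedo(scaled) == pytest.approx(
            k * core.broadband_albedo(base), rel=1e-12)

    @given(k=st.floats(0.01, 100.0))
    def test_common_rescaling_invariance(self, grid, k):
        """Albedo is invariant to a common rescale of canopy and panel."""
        panel = np.linspace(10, 100, len(grid))
        a1 = core.broadband_albedo(core.apply_water_mask(
            core.compute_reflectance(_sample(0.2 * panel), panel)))
        a2 = core.broadband_albedo(core.apply_water_mask(
            core.compute_reflectance(_sample(k * 0.2 * panel), k * panel)))
        assert a2 == pytest.approx(a1, rel=1e-12)


class TestPlotAlbedo:
    def test_constant_captures(self):
        obs = core.plot_albedo([0.2, 0.2, 0.2, 0.2], "P1", "noon")
        assert obs.albedo == 0.2 and obs.sem == 0.0 and obs.n_captures == 4

    def test_two_capture_sem(self):
        obs = core.plot_albedo([0.1, 0.3], "P1", "noon")
        assert obs.albedo == pytest.approx(0.2)
        # sd = 0.1414..., / sqrt(2) = 0.1
        assert obs.sem == pytest.approx(0.1)

    def test_single_capture(self):
        obs = core.plot_albedo([0.17], "P1", "noon")
        assert obs.albedo == 0.17 and obs.sem == 0.0 and obs.n_captures == 1


class TestDayPeriod:
    @pytest.mark.parametrize(
        "hh,mm,expected",
        [(12, 0, "noon"), (8, 30, "morning"), (13, 30, "other"),
         (11, 0, "noon"), (13, 0, "other"), (14, 30, "afternoon")],
    )
    def test_labels(self, hh, mm, expected):
        t = datetime(2018, 10, 1, hh, mm, tzinfo=timezone.utc)
        assert core.assign_day_period(t) == expected

    def test_overlapping_windows_rejected(self):
        from datetime import time
        with pytest.raises(ConfigError):
            core.PeriodWindows(morning=(time(8), time(12)), noon=(time(11), time(13)))
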