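"""Edge fitting, evaporative fraction, soil heat flux, and daily upscaling."""

import numpy as np
import pytest

from etcmp.constants import LATENT_HEAT_VAPORIZATION
from etcmp.ssebi import (EdgeModel, daylength, evaporative_fraction, fit_edges,
                         instantaneous_to_daily, latent_to_et_instant,
                         partition_energy, soil_heat_flux)
from etcmp.synthetic import SceneTruth, gen_scene

TRUE_EDGES = SceneTruth().edges


class TestFitEdges:
    def test_noiseless_recovery_is_exact(self):
        sc = gen_scene(n_pixels=5000, sigma_t=0.0, seed=42)
        em = fit_edges(sc.albedo, sc.ts, sc.ndvi)
        assert em.a_h == pytest.approx(TRUE_EDGES.a_h, abs=1e-6)
        assert em.b_h == pytest.approx(TRUE_EDGES.b_h, abs=1e-5)
        assert em.a_le == pytest.approx(TRUE_EDGES.a_le, abs=1e-6)
        assert em.b_le == pytest.approx(TRUE_EDGES.b_le, abs=1e-5)

    def test_noisy_recovery_within_tolerance(self):
        sc = gen_scene(n_pixels=5000, sigma_t=0.5, seed=42)
        em = fit_edges(sc.albedo, sc.ts, sc.ndvi)
        assert em.b_h == pytest.approx(TRUE_EDGES.b_h, rel=0.05)
        assert em.b_le == pytest.approx(TRUE_EDGES.b_le, rel=0.05)
        assert em.a_h == pytest.approx(TRUE_EDGES.a_h, abs=1.0)
        assert em.a_le == pytest.approx(TRUE_EDGES.a_le, abs=1.0)

    def test_degenerate_albedo_raises(self):
        n = 1000
        alpha = np.full(n, 0.25)
        ts = np.linspace(290, 320, n)
        with pytest.raises(ValueError, match="insufficient"):
            fit_edges(alpha, ts, np.full(n, 0.6))

    def test_too_few_pixels_raises(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_edges(np.linspace(0.1, 0.4, 50), np.linspace(300, 310, 50))


class TestEvaporativeFraction:
    @pytest.mark.parametrize("where,expected", [("dry", 0.0), ("wet", 1.0),
                                                ("mid", 0.5)])
    def test_anchor_positions(self, where, expected):
        alpha = 0.3
        th, tw = TRUE_EDGES.t_dry(alpha), TRUE_EDGES.t_wet(alpha)
        ts = {"dry": th, "wet": tw, "mid": 0.5 * (th + tw)}[where]
        assert evaporative_fraction(ts, alpha, TRUE_EDGES) == pytest.approx(expected)

    def test_clipping_reported(self):
        alpha = np.array([0.3, 0.3])
        ts = np.array([TRUE_EDGES.t_dry(0.3) + 5.0, 300.0])  # one beyond dry edge
        lam, clipped = evaporative_fraction(ts, alpha, TRUE_EDGES,
                                            return_clipped_fraction=True)
        assert lam[0] == 0.0
        assert clipped == pytest.approx(0.5)

    def test_invalid_edges_raise(self):
        bad = EdgeModel(300.0, 0.0, 310.0, 0.0)
        with pytest.raises(ValueError, match="invalid edges"):
            evaporative_fraction(305.0, 0.2, bad)


class TestSoilHeatFlux:
    def test_sob_at_zero_msavi(self):
        assert soil_heat_flux("SOB", 1.0, msavi=0.0) == pytest.approx(0.5)

    def test_const_ratio(self):
        assert soil_heat_flux("CONST", 500.0) == pytest.approx(100.0)

    def test_clo_equal_bands(self):
        assert soil_heat_flux("CLO", 1.0, rho_nir=0.2, rho_red=0.2) \
            == pytest.approx(0.295 - 0.01331)

    def test_sentinel_paths(self):
        assert np.isnan(soil_heat_flux("CLO", 100.0, rho_nir=0.3, rho_red=0.0))
        assert np.isnan(soil_heat_flux("DAU", 100.0, ts=300.0, alpha=0.0, ndvi=0.5))

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="unknown G0 model"):
            soil_heat_flux("XYZ", 100.0)

    def test_dau_gives_highest_ratio_on_synthetic_scene(self):
        sc = gen_scene(n_pixels=2000, sigma_t=0.5, seed=3)
        rn = np.full_like(sc.albedo, 500.0)
        ratios = {}
        for m in ("CLO", "DAU", "BAS", "SOB", "CONST"):
            g0 = soil_heat_flux(m, rn, ts=sc.ts, alpha=sc.albedo, ndvi=sc.ndvi,
                                msavi=sc.msavi, rho_nir=sc.rho_nir,
                                rho_red=sc.rho_red)
            ratios[m] = float(np.nanmean(g0)) / 500.0
        assert ratios["DAU"] == max(ratios.values())


class TestPartitionAndConversion:
    def test_partition_limits(self):
        assert partition_energy(500.0, 100.0, 1.0) == (400.0, 0.0)
        assert partition_energy(500.0, 100.0, 0.0)[0] == 0.0
        le, h = partition_energy(500.0, 100.0, 0.5)
        assert le == h == 200.0

    def test_negative_available_energy_zeroed(self):
        le, h = partition_energy(100.0, 150.0, 0.7)
        assert le == 0.0
        assert le + h + 150.0 == pytest.approx(100.0)  # closure maintained

    def test_energy_closure_all_models(self):
        sc = gen_scene(n_pixels=3000, sigma_t=0.5, seed=7)
        rn = 450.0 - 300.0 * sc.albedo
        lam = sc.lam_true
        for m in ("CLO", "DAU", "BAS", "SOB", "CONST"):
            g0 = soil_heat_flux(m, rn, ts=sc.ts, alpha=sc.albedo, ndvi=sc.ndvi,
                                msavi=sc.msavi, rho_nir=sc.rho_nir,
                                rho_red=sc.rho_red)
            le, h = partition_energy(rn, g0, lam)
            assert np.nanmax(np.abs(g0 + h + le - rn)) < 1e-6

    def test_latent_to_et_unit_inversion(self):
        assert latent_to_et_instant(0.0) == 0.0
        le_1mm = LATENT_HEAT_VAPORIZATION / 3600.0
        assert latent_to_et_instant(le_1mm) == pytest.approx(1.0)
        assert latent_to_et_instant(le_1mm / 2) == pytest.approx(0.5)


class TestDailyUpscaling:
    def test_noon_overpass(self):
        assert instantaneous_to_daily(1.0, 6.0, 12.0) == pytest.approx(24.0 / np.pi)
        assert instantaneous_to_daily(0.0, 3.0, 12.0) == 0.0

    def test_outside_daylight(self):
        with pytest.raises(ValueError, match="daylight"):
            instantaneous_to_daily(1.0, 13.0, 12.0)

    def test_consistency_with_integrated_sinusoid(self):
        # diurnal course ET(t) = ETmax sin(pi t / N): the daily estimate from
        # any single overpass must equal the numerically integrated total
        n_day = 11.0
        et_max = 0.9
        tt = np.linspace(0.0, n_day, 20001)
        total = np.trapezoid(et_max * np.sin(np.pi * tt / n_day), tt)
        for t in np.linspace(0.1 * n_day, 0.9 * n_day, 9):
            et_i = et_max * np.sin(np.pi * t / n_day)
            est = instantaneous_to_daily(et_i, t, n_day)
            assert est == pytest.approx(total, rel=1e-3)

    def test_monotone_in_lambda(self):
        avail = 400.0
        ets = [instantaneous_to_daily(
            latent_to_et_instant(lam * avail), 4.0, 12.0)
            for lam in (0.2, 0.5, 0.8)]
        assert ets[0] < ets[1] < ets[2]


class TestDaylength:
    def test_equator(self):
        assert daylength(0.0, 80) == pytest.approx(12.0, abs=0.1)
        assert daylength(0.0, 200) == pytest.approx(12.0, abs=0.1)

    def test_midlatitude(self):
        assert daylength(36.48, 80) == pytest.approx(12.0, abs=0.25)  # equinox
        assert daylength(36.48, 172) > 14.0                           # solstice

    def test_polar_rejected(self):
        with pytest.raises(ValueError, match="polar"):
            daylength(70.0, 100)
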