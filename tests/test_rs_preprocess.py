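"""Reflectance, albedo, vegetation index, and net radiation operations."""

from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etcmp.constants import ALBEDO_WEIGHTS, STEFAN_BOLTZMANN
from etcmp.rs_preprocess import (SpectralScene, albedo, msavi, ndvi,
                                 net_radiation, radiation_budget,
                                 toa_reflectance)

FLOATS01 = st.floats(0.0, 1.0)


def _scene(value=0.2, ts=300.0, shape=(4, 5)):
    bands = {b: np.full(shape, value) for b in ALBEDO_WEIGHTS}
    return SpectralScene(
        reflectance=bands,
        surface_temperature=np.full(shape, ts),
        acquisition_time=datetime(2016, 4, 1, 10, 30, tzinfo=timezone.utc),
        solar_zenith=0.5,
        latitude=36.48,
    )


class TestToaReflectance:
    @pytest.mark.parametrize("radiance,d,kdown,zenith,expected", [
        (0.0, 1.0, 1500.0, 0.3, 0.0),
        (100.0, 1.0, 2000.0, 0.0, np.pi * 100 / 2000),
    ])
    def test_values(self, radiance, d, kdown, zenith, expected):
        assert toa_reflectance(radiance, d, kdown, zenith) == pytest.approx(expected)

    def test_identity_case_gives_unity(self):
        # radiance chosen so pi L d^2 exactly equals K cos(theta)
        kdown, zen = 1800.0, 0.4
        L = kdown * np.cos(zen) / np.pi
        assert toa_reflectance(L, 1.0, kdown, zen) == pytest.approx(1.0)

    def test_out_of_range_clipped_not_raised(self):
        assert toa_reflectance(1e5, 1.0, 100.0, 0.0) == 1.0

    def test_sun_below_horizon(self):
        with pytest.raises(ValueError, match="horizon"):
            toa_reflectance(10.0, 1.0, 1500.0, np.pi / 2)


class TestAlbedo:
    def test_weights_sum_to_one(self):
        assert sum(ALBEDO_WEIGHTS.values()) == pytest.approx(1.0, abs=1e-12)

    def test_flat_spectrum_returns_same_value(self):
        bands = {b: 0.2 for b in ALBEDO_WEIGHTS}
        assert albedo(bands) == pytest.approx(0.2)

    def test_single_band_contribution(self):
        bands = {b: (1.0 if b == "B2" else 0.0) for b in ALBEDO_WEIGHTS}
        assert albedo(bands) == pytest.approx(0.293)

    def test_missing_band_named(self):
        bands = {b: 0.1 for b in ALBEDO_WEIGHTS if b != "B6"}
        with pytest.raises(KeyError, match="B6"):
            albedo(bands)

    @given(c=FLOATS01, rho=FLOATS01)
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, c, rho):
        bands = {b: rho for b in ALBEDO_WEIGHTS}
        scaled = {b: c * rho for b in ALBEDO_WEIGHTS}
        assert albedo(scaled) == pytest.approx(c * albedo(bands), abs=1e-12)


class TestVegetationIndices:
    def test_ndvi_values(self):
        assert ndvi(0.3, 0.3) == 0.0
        assert ndvi(0.4, 0.1) == pytest.approx(0.6)
        assert np.isnan(ndvi(0.0, 0.0))

    def test_msavi_values(self):
        assert msavi(0.25, 0.25) == pytest.approx(0.0, abs=1e-12)
        assert msavi(0.4, 0.1) == pytest.approx((1.8 - np.sqrt(3.24 - 2.4)) / 2)
        assert msavi(1.0, 0.0) == pytest.approx(1.0)

    @given(nir=FLOATS01, red=FLOATS01)
    @settings(max_examples=100, deadline=None)
    def test_indices_bounded(self, nir, red):
        v = ndvi(nir, red)
        if not np.isnan(v):
            assert -1.0 <= v <= 1.0
        assert -1.0 <= msavi(nir, red) <= 1.0


class TestNetRadiation:
    def test_cancellation(self):
        assert net_radiation(1.0, 800.0, 300.0, 0.9, ta=300.0,
                             emissivity_atmosphere=0.9) == pytest.approx(0.0)
        assert net_radiation(0.3, 0.0, 290.0, 1.0, ta=290.0,
                             emissivity_atmosphere=1.0) == pytest.approx(0.0)

    def test_reference_value(self):
        # term-by-term: 0.8*800 - 0.98 sigma 300^4 + 0.85 sigma 295^4
        expected = 640.0 - 0.98 * STEFAN_BOLTZMANN * 300.0 ** 4 \
            + 0.85 * STEFAN_BOLTZMANN * 295.0 ** 4
        got = net_radiation(0.2, 800.0, 300.0, 0.98, ta=295.0,
                            emissivity_atmosphere=0.85)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(555.0, abs=0.5)

    def test_monotone_in_albedo_and_ts(self):
        base = net_radiation(0.2, 800.0, 300.0, 0.98, ta=295.0,
                             emissivity_atmosphere=0.85)
        assert net_radiation(0.3, 800.0, 300.0, 0.98, ta=295.0,
                             emissivity_atmosphere=0.85) < base
        assert net_radiation(0.2, 800.0, 305.0, 0.98, ta=295.0,
                             emissivity_atmosphere=0.85) < base

    def test_bad_albedo(self):
        with pytest.raises(ValueError):
            net_radiation(1.3, 800.0, 300.0, 0.98, ta=295.0,
                          emissivity_atmosphere=0.85)


class TestSceneAndBudget:
    def test_raster_scalar_consistency(self):
        scene = _scene(0.2, 300.0)
        budget = radiation_budget(scene, rg=800.0, ta=295.0,
                                  emissivity_atmosphere=0.85)
        scalar = net_radiation(0.2, 800.0, 300.0, 0.98, ta=295.0,
                               emissivity_atmosphere=0.85)
        assert np.allclose(budget.net_radiation, scalar)
        assert np.allclose(budget.albedo, 0.2)

    def test_rn_upper_bound_invariant(self):
        scene = _scene(0.15, 310.0)
        b = radiation_budget(scene, rg=900.0, ta=300.0, vapor_pressure_kpa=1.8)
        upper = (1 - b.albedo) * b.solar_radiation + b.incoming_longwave
        assert np.all(b.net_radiation <= upper)

    def test_scene_validation(self):
        with pytest.raises(ValueError, match="kelvin"):
            _scene(0.2, ts=25.0)
        bands = {b: np.full((2, 2), 0.1) for b in ALBEDO_WEIGHTS}
        bands["B3"] = np.full((3, 2), 0.1)
        with pytest.raises(ValueError, match="shape"):
            SpectralScene(bands, np.full((2, 2), 300.0),
                          datetime(2016, 1, 1), 0.3, 36.0)
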