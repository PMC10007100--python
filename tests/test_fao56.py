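"""Reference ET, crop coefficients, LAI transfer, and the E/T split."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etcmp import fao56


def reference_day_et0():
    """Independent step-by-step computation of the standardized daily
    reference-ET equation for the classic mid-latitude July reference day
    (Tmax 21.5 / Tmin 12.3 degC, RH 84/63 %, u2 2.078 m/s, 9.25 sunshine
    hours, lat 50.8 N, 100 m elevation)."""
    tmax, tmin = 21.5, 12.3
    tmean = (tmax + tmin) / 2
    es_tmax = 0.6108 * np.exp(17.27 * tmax / (tmax + 237.3))
    es_tmin = 0.6108 * np.exp(17.27 * tmin / (tmin + 237.3))
    es = (es_tmax + es_tmin) / 2
    ea = (es_tmin * 0.84 + es_tmax * 0.63) / 2
    delta = 4098 * (0.6108 * np.exp(17.27 * tmean / (tmean + 237.3))) \
        / (tmean + 237.3) ** 2
    p = 101.3 * ((293 - 0.0065 * 100.0) / 293) ** 5.26
    gamma = 0.000665 * p
    doy = 187
    phi = np.radians(50.8)
    dr = 1 + 0.033 * np.cos(2 * np.pi / 365 * doy)
    decl = 0.409 * np.sin(2 * np.pi / 365 * doy - 1.39)
    ws = np.arccos(-np.tan(phi) * np.tan(decl))
    ra = 24 * 60 / np.pi * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws))
    n_max = 24 / np.pi * ws
    rs = (0.25 + 0.50 * 9.25 / n_max) * ra
    rso = (0.75 + 2e-5 * 100.0) * ra
    rns = 0.77 * rs
    rnl = 4.903e-9 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2 \
        * (0.34 - 0.14 * np.sqrt(ea)) * (1.35 * rs / rso - 0.35)
    rn = rns - rnl
    u2 = 2.078
    et0 = (0.408 * delta * rn + gamma * 900 / (tmean + 273) * u2 * (es - ea)) \
        / (delta + gamma * (1 + 0.34 * u2))
    return float(et0), float(rs)


class TestET0:
    def test_reference_day_vs_independent_computation(self):
        expected, rs = reference_day_et0()
        meteo = pd.DataFrame([{
            "date": "2000-07-06", "Ta_min": 12.3, "Ta_max": 21.5,
            "RH_min": 63.0, "RH_max": 84.0, "RH_mean": 73.5,
            "Rg": rs, "wind_2m": 2.078,
        }])
        got = fao56.et0_penman_monteith(meteo, latitude=50.8, elevation=100.0)
        assert got.iloc[0] == pytest.approx(expected, rel=0.05)
        assert expected == pytest.approx(3.88, abs=0.15)  # sanity on the oracle

    def test_no_demand_gives_near_zero(self):
        meteo = pd.DataFrame([{
            "date": "2000-01-15", "Ta_min": 10.0, "Ta_max": 10.0,
            "RH_mean": 100.0, "Rg": 0.0, "wind_2m": 0.0,
        }])
        assert fao56.et0_penman_monteith(meteo, 36.5).iloc[0] <= 0.05

    def test_wind_increases_demand_under_vpd(self):
        base = {"date": "2000-07-01", "Ta_min": 20.0, "Ta_max": 34.0,
                "RH_mean": 30.0, "Rg": 25.0}
        low = fao56.et0_penman_monteith(
            pd.DataFrame([{**base, "wind_2m": 1.5}]), 36.5).iloc[0]
        high = fao56.et0_penman_monteith(
            pd.DataFrame([{**base, "wind_2m": 3.0}]), 36.5).iloc[0]
        assert high > low

    def test_missing_column_named(self):
        meteo = pd.DataFrame([{"date": "2000-07-01", "Ta_min": 10.0,
                               "Ta_max": 20.0, "RH_mean": 50.0, "Rg": 20.0}])
        with pytest.raises(KeyError, match="wind_2m"):
            fao56.et0_penman_monteith(meteo, 36.5)


@pytest.fixture(scope="module")
def barley_calendar():
    return fao56.CropCalendar(
        crop="barley", planting=date(2016, 10, 18), harvest=date(2017, 6, 20),
        kc_ini=0.3, kc_mid=1.15, kc_end=0.25,
        stage_fractions=(0.25, 0.25, 0.30, 0.20),
        lai_points=[(0.0, 0.29), (0.5, 3.5), (0.8, 3.5), (1.0, 0.29)],
    )


class TestKcInterpolation:
    def test_stage_values(self, barley_calendar):
        assert fao56.kc_interpolate(barley_calendar, date(2016, 10, 18)) == 0.3
        mid = date(2017, 4, 1)  # within mid stage (fraction ~0.66)
        assert fao56.kc_interpolate(barley_calendar, mid) == 1.15
        assert fao56.kc_interpolate(barley_calendar, date(2017, 6, 20)) == 0.25

    def test_potato_mid(self, potato_calendar):
        assert fao56.kc_interpolate(potato_calendar, date(2015, 5, 20)) == 1.15

    def test_continuity_across_breakpoints(self, barley_calendar):
        dates = pd.date_range(barley_calendar.planting,
                              barley_calendar.harvest, freq="D")
        kcs = np.array([fao56.kc_interpolate(barley_calendar, d) for d in dates])
        assert np.max(np.abs(np.diff(kcs))) < 0.04  # no jumps, daily steps only

    def test_outside_season(self, barley_calendar):
        with pytest.raises(ValueError, match="season"):
            fao56.kc_interpolate(barley_calendar, date(2016, 6, 1))


class TestCoefficientForms:
    def test_etc_single(self):
        assert fao56.etc_single(1.15, 5.0) == pytest.approx(5.75)
        assert fao56.etc_single(0.8, 0.0) == 0.0
        assert fao56.etc_single(1.0, 3.2) == 3.2

    def test_eta_dual(self):
        assert fao56.eta_dual(1.0, 0.9, 0.2, 4.0) == pytest.approx(4.4)
        assert fao56.eta_dual(0.0, 0.9, 0.0, 4.0) == 0.0
        assert fao56.eta_dual(0.5, 1.0, 0.2, 4.0) == pytest.approx(2.8)

    def test_lai_from_ndvi(self):
        assert fao56.lai_from_ndvi(4.58 / 7.33) == pytest.approx(1.0)
        assert fao56.lai_from_ndvi(0.0) == pytest.approx(np.exp(-4.58))
        ndvis = np.linspace(0.0, 0.9, 10)
        assert np.all(np.diff(fao56.lai_from_ndvi(ndvis)) > 0)


class TestPartitionET:
    def test_bare_soil_and_full_cover(self):
        t, e = fao56.partition_et(5.0, 0.0)
        assert t == 0.0 and e == 5.0
        t, e = fao56.partition_et(5.0, 3.5)
        assert t / 5.0 == pytest.approx(1 - np.exp(-0.46 * 3.5))
        assert t / 5.0 == pytest.approx(0.80, abs=0.005)

    @given(etc=st.floats(0.0, 12.0), lai=st.floats(0.0, 8.0))
    @settings(max_examples=200, deadline=None)
    def test_conservation(self, etc, lai):
        t, e = fao56.partition_et(etc, lai)
        assert t + e == pytest.approx(etc, abs=1e-12)
        assert t >= 0.0 and e >= 0.0


class TestSeasonStability:
    def test_seasonal_cwr_stable_under_small_length_changes(self, barley_calendar):
        """Shifting harvest by a few days must not swing the seasonal crop
        water requirement (stage interpolation is smooth)."""
        def cwr(harvest_shift):
            cal = fao56.CropCalendar(
                crop="barley", planting=barley_calendar.planting,
                harvest=barley_calendar.harvest + pd.Timedelta(days=harvest_shift),
                kc_ini=0.3, kc_mid=1.15, kc_end=0.25,
                stage_fractions=barley_calendar.stage_fractions)
            dates = cal.dates()
            return sum(fao56.kc_interpolate(cal, d) * 3.0 for d in dates)
        base = cwr(0)
        assert abs(cwr(3) - base) / base < 0.15
        assert abs(cwr(-3) - base) / base < 0.15
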