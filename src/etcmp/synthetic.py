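"""Synthetic inputs with known truth for every stage of the pipeline.

Every generator is a pure function of its parameters and a seed. The scene
generator emulates the trapezoidal (albedo, surface temperature) scatter
that contextual energy-balance methods rely on - including the presence of
extreme pixels on both envelopes, without which the method's premise (a
dry and a wet limit visible in the scene) does not hold. The meteorology
generator is calibrated to a semi-arid Mediterranean climate with ~450 mm
expected annual rainfall and an annual grass-reference ET around 1.4 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

from .ssebi import EdgeModel
from . import fao56

__all__ = ["SceneTruth", "SyntheticScene", "gen_scene", "gen_meteo",
           "gen_forcing_fixtures", "gen_sensor_obs", "SEASONS"]


@dataclass
class SceneTruth:
    """Ground truth behind one synthetic scene."""

    edges: EdgeModel = field(default_factory=lambda: EdgeModel(
        a_h=330.0, b_h=-25.0, a_le=288.0, b_le=10.0, albedo_domain=(0.10, 0.45)))
    n_pixels: int = 5000
    sigma_t: float = 0.0          # K, Gaussian noise on Ts
    sigma_ndvi: float = 0.03
    anchor_fraction: float = 0.02  # fraction of pixels pinned on each edge
    seed: int = 0


@dataclass
class SyntheticScene:
    """Rasters of one generated acquisition plus its truth record."""

    albedo: np.ndarray
    ts: np.ndarray
    ndvi: np.ndarray
    rho_nir: np.ndarray
    rho_red: np.ndarray
    lam_true: np.ndarray
    truth: SceneTruth

    @property
    def msavi(self) -> np.ndarray:
        from .rs_preprocess import msavi
        return msavi(self.rho_nir, self.rho_red)


def gen_scene(truth: SceneTruth | None = None, **kwargs) -> SyntheticScene:
    """Generate one scene from a known edge geometry.

    Albedo ~ U over the edge model's domain; true evaporative fraction
    Lambda ~ Beta(2, 2); Ts = (1-Lambda) T_dry(a) + Lambda T_wet(a) +
    N(0, sigma_t). A small albedo-stratified fraction of pixels is pinned
    exactly on each envelope (Lambda = 0 and 1): contextual retrieval
    presumes such extremes exist in-scene. NDVI = 0.3 + 0.5 Lambda +
    N(0, sigma_ndvi), clipped to [0.3, 0.95] so an NDVI >= 0.3 mask keeps
    every pixel; red/NIR reflectance are back-solved from NDVI under
    rho_NIR + rho_R = 0.5.
    """
    truth = truth or SceneTruth(**kwargs)
    if truth.n_pixels < 1:
        raise ValueError("need at least one pixel")
    edges = truth.edges
    a_lo, a_hi = edges.albedo_domain
    if edges.t_dry(a_lo) <= edges.t_wet(a_lo) or edges.t_dry(a_hi) <= edges.t_wet(a_hi):
        raise ValueError("edge lines cross inside the albedo domain")
    rng = np.random.default_rng(truth.seed)
    n = truth.n_pixels

    alpha = rng.uniform(a_lo, a_hi, n)
    lam = rng.beta(2.0, 2.0, n)

    n_anchor = max(2, int(round(truth.anchor_fraction * n))) if n >= 8 else 0
    if n_anchor and 2 * n_anchor < n:
        grid = np.linspace(a_lo, a_hi, n_anchor)
        alpha[:n_anchor] = grid
        lam[:n_anchor] = 0.0
        alpha[n_anchor:2 * n_anchor] = grid
        lam[n_anchor:2 * n_anchor] = 1.0

    ts = (1.0 - lam) * edges.t_dry(alpha) + lam * edges.t_wet(alpha)
    if truth.sigma_t > 0:
        ts = ts + rng.normal(0.0, truth.sigma_t, n)
    ndvi = np.clip(0.3 + 0.5 * lam + rng.normal(0.0, truth.sigma_ndvi, n), 0.3, 0.95)
    rho_nir = 0.25 * (1.0 + ndvi)
    rho_red = 0.25 * (1.0 - ndvi)
    return SyntheticScene(albedo=alpha, ts=ts, ndvi=ndvi, rho_nir=rho_nir,
                          rho_red=rho_red, lam_true=lam, truth=truth)


def gen_meteo(year: int, latitude: float = 36.48, seed: int = 0) -> pd.DataFrame:
    """One calendar year of daily weather for a semi-arid coastal site.

    Sinusoidal air temperature (daily means ~8 degC mid-winter to ~32 degC
    mid-summer), shortwave radiation as a clear-sky fraction of
    extraterrestrial radiation with multiplicative noise and cloudy rain
    days, relative humidity anticorrelated with temperature, lognormal
    wind, and winter-weighted Poisson rain occurrence with gamma depths
    scaled to an expected 450 mm per year.

    Columns: date, Ta_mean, Ta_min, Ta_max, Rg [MJ m-2 d-1], RH_mean,
    wind_2m, precipitation [mm].
    """
    rng = np.random.default_rng(seed)
    dates = pd.date_range(_date(year, 1, 1), _date(year, 12, 31), freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    n = len(dates)

    ta_mean = 20.0 + 12.0 * np.cos(2 * np.pi * (doy - 196.0) / 365.0) \
        + rng.normal(0.0, 1.5, n)
    ta_max = ta_mean + 5.5 + rng.normal(0.0, 0.8, n)
    ta_min = ta_mean - 5.5 + rng.normal(0.0, 0.8, n)

    # rainfall: mean annual total 450 mm = E[events] * E[depth]
    mean_depth = 8.0      # gamma(k=0.8, theta=10)
    p0 = 450.0 / mean_depth / 365.0
    p_rain = p0 * (1.0 + 0.8 * np.cos(2 * np.pi * (doy - 15.0) / 365.0))
    wet = rng.uniform(size=n) < p_rain
    precip = np.where(wet, rng.gamma(0.8, mean_depth / 0.8, n), 0.0)

    ra = fao56.extraterrestrial_radiation(latitude, doy)
    kt = np.clip(0.72 + rng.normal(0.0, 0.05, n), 0.30, 0.78)
    kt = np.where(wet, kt * 0.55, kt)
    rg = kt * np.asarray(ra)

    rh = np.clip(68.0 - 1.2 * (ta_mean - 20.0) + 12.0 * wet
                 + rng.normal(0.0, 5.0, n), 25.0, 100.0)
    wind = rng.lognormal(np.log(1.9), 0.4, n)

    return pd.DataFrame({
        "date": dates, "Ta_mean": ta_mean, "Ta_min": ta_min, "Ta_max": ta_max,
        "Rg": rg, "RH_mean": rh, "wind_2m": wind, "precipitation": precip,
    })


#: The three monitored cropping seasons: (crop, planting, harvest,
#: irrigation total mm, number of events, rainfall total mm).
SEASONS = {
    1: ("potato", _date(2015, 3, 11), _date(2015, 7, 7), 336.0, 16, 20.0),
    2: ("potato", _date(2016, 1, 18), _date(2016, 5, 17), 170.0, 8, 70.0),
    3: ("barley", _date(2016, 10, 18), _date(2017, 6, 20), 0.0, 0, 291.0),
}

#: Salinity of the irrigation water [dS m-1].
IRRIGATION_EC = 3.5


def gen_forcing_fixtures(latitude: float = 36.48, seed: int = 0,
                         elevation: float = 20.0) -> dict[int, pd.DataFrame]:
    """Daily forcing for the three seasons, with the documented totals.

    Irrigation is split into equal events evenly spaced through the
    development + mid stages (drip scheduling); rainfall is split into
    equal events evenly spaced over the wet part of the season (the whole
    season for the potato crops, planting through April for the rainfed
    winter barley). ET0 is computed from :func:`gen_meteo` weather for the
    matching calendar years.

    Returns {season_number: DataFrame(date, precipitation, irrigation,
    irrigation_EC, ET0, ...weather columns)}.
    """
    out = {}
    meteo_by_year = {}
    for season, (crop, start, end, irr_total, n_events, rain_total) in SEASONS.items():
        dates = pd.date_range(start, end, freq="D")
        years = sorted({d.year for d in dates})
        parts = []
        for y in years:
            if y not in meteo_by_year:
                meteo_by_year[y] = gen_meteo(y, latitude, seed=seed + y)
            parts.append(meteo_by_year[y])
        meteo = pd.concat(parts, ignore_index=True)
        meteo = meteo[meteo["date"].isin(dates)].reset_index(drop=True)
        et0 = fao56.et0_penman_monteith(meteo, latitude, elevation)

        irrigation = np.zeros(len(dates))
        if n_events:
            # events across the 20%..80% span of the season
            idx = np.linspace(0.20, 0.80, n_events) * (len(dates) - 1)
            for i in np.round(idx).astype(int):
                irrigation[i] += irr_total / n_events
        rain = np.zeros(len(dates))
        if rain_total > 0:
            if crop == "barley":
                wet_end = np.searchsorted(dates, pd.Timestamp(2017, 4, 30))
            else:
                wet_end = len(dates) - 1
            n_rain = max(4, int(round(rain_total / 12.0)))
            idx = np.linspace(0.0, 1.0, n_rain) * (wet_end - 1)
            for i in np.round(idx).astype(int):
                rain[i] += rain_total / n_rain

        df = pd.DataFrame({
            "date": dates,
            "precipitation": rain,
            "irrigation": irrigation,
            "irrigation_EC": np.where(irrigation > 0, IRRIGATION_EC, 0.0),
            "ET0": et0.to_numpy(),
        })
        for col in ("Ta_mean", "Ta_min", "Ta_max", "Rg", "RH_mean", "wind_2m"):
            df[col] = meteo[col].to_numpy()
        out[season] = df
    return out


def gen_sensor_obs(daily: pd.DataFrame, depths=(0.05, 0.25, 0.45, 0.90),
                   theta_noise: float = 0.01, ec_noise_frac: float = 0.05,
                   seed: int = 0) -> pd.DataFrame:
    """Capacitance-sensor-like hourly theta/EC series at fixed depths.

    ``daily`` must come from :func:`simulate_season` run with
    ``record_profiles=True`` (nodal snapshots in ``daily.attrs``). Daily
    nodal profiles are linearly interpolated to hourly resolution at the
    nearest node to each requested depth; additive N(0, theta_noise)
    [m3 m-3] and multiplicative (1 + N(0, ec_noise_frac)) EC noise emulate
    the probes. Set both noise levels to 0 for noise-free sampling.
    """
    profiles = daily.attrs.get("profiles")
    if profiles is None:
        raise ValueError("daily table has no nodal profiles; rerun the season "
                         "with record_profiles=True")
    node_depths = np.asarray(profiles["depths"])
    for d in depths:
        if d < node_depths.min() - 1e-9 or d > node_depths.max() + 1e-9:
            raise ValueError(f"depth {d} m outside the simulated profile")
    rng = np.random.default_rng(seed)
    dates = pd.to_datetime(profiles["dates"])
    theta = np.asarray(profiles["theta"])  # (days, nodes)
    ec = np.asarray(profiles["ec"])

    hours = pd.date_range(dates[0], dates[-1], freq="h")
    t_day = (dates - dates[0]).total_seconds().to_numpy() / 86400.0
    t_hr = (hours - dates[0]).total_seconds().to_numpy() / 86400.0

    rows = {}
    for d in depths:
        j = int(np.argmin(np.abs(node_depths - d)))
        th = np.interp(t_hr, t_day, theta[:, j])
        e = np.interp(t_hr, t_day, ec[:, j])
        if theta_noise > 0:
            th = th + rng.normal(0.0, theta_noise, len(th))
        if ec_noise_frac > 0:
            e = e * (1.0 + rng.normal(0.0, ec_noise_frac, len(e)))
        rows[f"theta_{d:.2f}m"] = np.maximum(th, 0.0)
        rows[f"EC_{d:.2f}m"] = np.maximum(e, 0.0)
    return pd.DataFrame(rows, index=hours)
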