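"""Scenario grid, comparison statistics, and the flux comparison table.

Scenario naming: ``S{1,2,3}`` prefixes are the satellite energy-balance
route with the soil-heat-flux model varying (S1 = CLO, S2 = BAS,
S3 = SOB); ``F`` prefixes are the FAO-56 single-coefficient baseline; ``H``
prefixes the soil-water simulation route. Suffixes ``P1``/``P2`` are the
two potato seasons (2015, 2016) and ``B`` the rainfed barley season; the
barley simulation comes in two leaf-area variants (H1B literature LAI,
H2B NDVI-derived LAI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fao56, presets, synthetic
from .rs_preprocess import net_radiation
from .ssebi import (EdgeFitConfig, daylength, evaporative_fraction, fit_edges,
                    instantaneous_to_daily, latent_to_et_instant,
                    partition_energy, soil_heat_flux)
from .soil import simulate_season

__all__ = [
    "ScenarioID", "SCENARIOS", "run_scenario",
    "rmse", "r_squared", "nse", "compare_series",
    "scene_fluxes", "g0_comparison_table", "build_scene_records",
]


@dataclass(frozen=True)
class ScenarioID:
    id: str
    method: str          # SSEBI | FAO56 | SOIL
    season: int          # 1, 2, 3
    g0_model: str | None = None
    lai_mode: str = "literature"

    @property
    def crop(self) -> str:
        return synthetic.SEASONS[self.season][0]


def _grid() -> dict[str, ScenarioID]:
    g0_by_s = {"S1": "CLO", "S2": "BAS", "S3": "SOB"}
    ids = {}
    for s, g0 in g0_by_s.items():
        for suffix, season in (("P1", 1), ("P2", 2), ("B", 3)):
            sid = f"{s}{suffix}"
            ids[sid] = ScenarioID(sid, "SSEBI", season, g0_model=g0)
    for sid, season in (("FP1", 1), ("FP2", 2), ("FB", 3)):
        ids[sid] = ScenarioID(sid, "FAO56", season)
    ids["HP1"] = ScenarioID("HP1", "SOIL", 1)
    ids["HP2"] = ScenarioID("HP2", "SOIL", 2)
    ids["H1B"] = ScenarioID("H1B", "SOIL", 3, lai_mode="literature")
    ids["H2B"] = ScenarioID("H2B", "SOIL", 3, lai_mode="ndvi")
    return ids


#: Registry of every scenario in the comparison grid.
SCENARIOS: dict[str, ScenarioID] = _grid()


def synthetic_ndvi_series(season: int) -> pd.Series:
    """Seasonal NDVI bell for the NDVI-driven LAI variant (0.30 -> 0.78)."""
    cal = presets.load_crop_calendar(season)
    dates = cal.dates()
    f = np.linspace(0.0, 1.0, len(dates))
    ndvi = 0.30 + 0.48 * np.sin(np.pi * f) ** 2
    return pd.Series(ndvi, index=dates)


def overpass_geometry(doy: int, latitude: float, overpass_solar_time: float = 10.5):
    """(Rg [W m-2], hours since sunrise, daylength) at a clear-sky overpass."""
    n = daylength(latitude, doy)
    phi = np.radians(latitude)
    decl = 0.409 * np.sin(2 * np.pi / 365 * doy - 1.39)
    omega = np.radians((overpass_solar_time - 12.0) * 15.0)
    cos_tz = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(omega)
    rg = 1367.0 * 0.75 * max(cos_tz, 0.0)
    t = overpass_solar_time - (12.0 - n / 2.0)
    return float(rg), float(t), float(n)


def scene_fluxes(scene, rg: float, ta: float, g0_model: str,
                 emissivity_surface: float = 0.98,
                 emissivity_atmosphere: float = 0.85,
                 edge_config: EdgeFitConfig | None = None) -> dict:
    """Full S-SEBI retrieval on one (synthetic or real) scene.

    ``scene`` needs albedo/ts/ndvi/msavi/rho_nir/rho_red rasters. Returns
    plot means of Rn, G0, lambdaE, H, Lambda plus the fitted edge
    coefficients and the clipped fraction.
    """
    edges = fit_edges(scene.albedo, scene.ts, scene.ndvi, edge_config)
    lam, clipped = evaporative_fraction(scene.ts, scene.albedo, edges,
                                        return_clipped_fraction=True)
    rn = net_radiation(scene.albedo, rg, scene.ts,
                       emissivity_surface=emissivity_surface,
                       ta=ta, emissivity_atmosphere=emissivity_atmosphere)
    g0 = soil_heat_flux(g0_model, rn, ts=scene.ts, alpha=scene.albedo,
                        ndvi=scene.ndvi, msavi=scene.msavi,
                        rho_nir=scene.rho_nir, rho_red=scene.rho_red)
    le, h = partition_energy(rn, g0, lam)
    return {
        "edges": edges, "clipped_fraction": clipped,
        "lam": float(np.nanmean(lam)), "rn": float(np.nanmean(rn)),
        "g0": float(np.nanmean(g0)), "le": float(np.nanmean(le)),
        "h": float(np.nanmean(h)),
        "lam_raster": lam, "rn_raster": rn, "g0_raster": g0, "le_raster": le,
    }


def _ssebi_series(sc: ScenarioID, seed: int, latitude: float = 36.48,
                  n_pixels: int = 3000, sigma_t: float = 0.5,
                  revisit_days: int = 16) -> pd.DataFrame:
    """Per-overpass S-SEBI ET for one season of synthetic scenes.

    Scene seeds depend only on (seed, season, overpass index), so scenarios
    differing only in the soil-heat-flux model see identical scenes.
    """
    cal = presets.load_crop_calendar(sc.season)
    dates = cal.dates()[::revisit_days]
    rows = []
    for i, date in enumerate(dates):
        doy = int(pd.Timestamp(date).dayofyear)
        scene_seed = (seed * 1009 + sc.season * 131 + i * 7) % (2 ** 31 - 1)
        scene = synthetic.gen_scene(n_pixels=n_pixels, sigma_t=sigma_t,
                                    seed=scene_seed)
        rg, t, n = overpass_geometry(doy, latitude)
        ta = 273.15 + 20.0 + 12.0 * np.cos(2 * np.pi * (doy - 196.0) / 365.0) + 3.0
        fx = scene_fluxes(scene, rg, ta, sc.g0_model)
        et_i = latent_to_et_instant(max(fx["le"], 0.0))
        et_a = instantaneous_to_daily(et_i, t, n)
        e = fx["edges"]
        rows.append({
            "date": date, "a_H": e.a_h, "b_H": e.b_h,
            "a_lE": e.a_le, "b_lE": e.b_le,
            "clipped_fraction": fx["clipped_fraction"],
            "lambda": fx["lam"], "Rn": fx["rn"], "G0": fx["g0"],
            "lE": fx["le"], "ET_a": float(et_a),
        })
    return pd.DataFrame(rows)


def run_scenario(scenario: str | ScenarioID, seed: int = 0, **kwargs) -> pd.DataFrame:
    """Run one scenario of the grid on the synthetic fixtures.

    Returns a DataFrame with at least ``date`` and ``ET_a`` columns (daily
    for the FAO-56 and soil routes, per-overpass for the satellite route).
    Fully determined by (scenario, seed).
    """
    if isinstance(scenario, str):
        try:
            sc = SCENARIOS[scenario.upper()]
        except KeyError:
            raise KeyError(
                f"unknown scenario {scenario!r}; valid ids: {sorted(SCENARIOS)}"
            ) from None
    else:
        sc = scenario

    if sc.method == "SSEBI":
        return _ssebi_series(sc, seed, **kwargs)

    forcing = synthetic.gen_forcing_fixtures(seed=seed)[sc.season]
    cal = presets.load_crop_calendar(sc.season)
    if sc.method == "FAO56":
        et0 = forcing.set_index("date")["ET0"]
        out = fao56.crop_series(cal, et0.to_numpy(), forcing["date"])
        out["ET_a"] = out["ETc"]  # unstressed baseline
        return out

    profile = presets.load_profile("oued_souhil")
    crop = presets.load_crop_params(sc.crop)
    ndvi_series = synthetic_ndvi_series(sc.season) if sc.lai_mode == "ndvi" else None
    daily = simulate_season(profile, crop, cal, forcing,
                            lai_mode=sc.lai_mode, ndvi_series=ndvi_series,
                            **kwargs)
    return daily


# ---------------------------------------------------------------------------
# Comparison statistics
# ---------------------------------------------------------------------------

def _paired(a: pd.Series, b: pd.Series):
    a = pd.Series(a).dropna()
    b = pd.Series(b).dropna()
    idx = a.index.intersection(b.index)
    return a.loc[idx].to_numpy(dtype=float), b.loc[idx].to_numpy(dtype=float)


def rmse(a: pd.Series, b: pd.Series) -> float:
    """Root-mean-square difference over the index intersection."""
    x, y = _paired(a, b)
    if len(x) < 1:
        raise ValueError("no paired dates for RMSE")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def r_squared(a: pd.Series, b: pd.Series) -> float:
    """Squared Pearson correlation over the index intersection."""
    x, y = _paired(a, b)
    if len(x) < 3:
        raise ValueError("need at least 3 paired dates for R2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a series")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def nse(sim: pd.Series, obs: pd.Series) -> float:
    """Nash-Sutcliffe efficiency of ``sim`` against ``obs`` (1 = perfect)."""
    s, o = _paired(sim, obs)
    if len(s) < 2:
        raise ValueError("need at least 2 paired dates for NSE")
    denom = np.sum((o - o.mean()) ** 2)
    if denom == 0:
        raise ValueError("zero variance in the reference series")
    return float(1.0 - np.sum((s - o) ** 2) / denom)


def compare_series(a: pd.DataFrame, b: pd.DataFrame,
                   column: str = "ET_a") -> dict:
    """RMSE / R2 / NSE between two scenario outputs on exact date matches."""
    sa = a.set_index("date")[column]
    sb = b.set_index("date")[column]
    return {"rmse": rmse(sa, sb), "r2": r_squared(sa, sb),
            "nse": nse(sa, sb), "n_pairs": len(sa.index.intersection(sb.index))}


# ---------------------------------------------------------------------------
# Soil-heat-flux model comparison (reference G0 = 0.2 Rn)
# ---------------------------------------------------------------------------

def build_scene_records(season: int, seed: int = 0, label: str | None = None,
                        latitude: float = 36.48, n_pixels: int = 3000,
                        sigma_t: float = 0.5, revisit_days: int = 16) -> list[dict]:
    """Per-overpass scene bundles (scene + Rn + Lambda) for one season."""
    cal = presets.load_crop_calendar(season)
    dates = cal.dates()[::revisit_days]
    label = label or synthetic.SEASONS[season][0]
    records = []
    for i, date in enumerate(dates):
        doy = int(pd.Timestamp(date).dayofyear)
        scene_seed = (seed * 1009 + season * 131 + i * 7) % (2 ** 31 - 1)
        scene = synthetic.gen_scene(n_pixels=n_pixels, sigma_t=sigma_t,
                                    seed=scene_seed)
        rg, _, _ = overpass_geometry(doy, latitude)
        ta = 273.15 + 20.0 + 12.0 * np.cos(2 * np.pi * (doy - 196.0) / 365.0) + 3.0
        fx = scene_fluxes(scene, rg, ta, "CONST")
        records.append({"label": label, "date": date, "scene": scene,
                        "rn": fx["rn_raster"], "lam": fx["lam_raster"]})
    return records


def g0_comparison_table(scene_records: list[dict],
                        g0_models=("CLO", "BAS", "SOB"),
                        reference: str = "CONST") -> pd.DataFrame:
    """RMSE of plot-mean G0 and lambdaE per model against a reference model.

    For each scene the plot-mean G0 and lambdaE are computed under every
    model (same Rn and Lambda rasters); each model's RMSE over scenes
    against the reference is reported, one row per scene-set label.
    """
    if len(scene_records) < 2:
        raise ValueError("need at least 2 scenes")
    per_scene = []
    for rec in scene_records:
        scene, rn, lam = rec["scene"], rec["rn"], rec["lam"]
        row = {"label": rec["label"]}
        for model in tuple(g0_models) + (reference,):
            g0 = soil_heat_flux(model, rn, ts=scene.ts, alpha=scene.albedo,
                                ndvi=scene.ndvi, msavi=scene.msavi,
                                rho_nir=scene.rho_nir, rho_red=scene.rho_red)
            le, _ = partition_energy(rn, g0, lam)
            row[f"G0_{model}"] = float(np.nanmean(g0))
            row[f"lE_{model}"] = float(np.nanmean(le))
        per_scene.append(row)
    df = pd.DataFrame(per_scene)

    rows = []
    for label, grp in df.groupby("label", sort=False):
        row = {"scenes": label, "n_dates": len(grp)}
        for model in g0_models:
            row[f"RMSE_G0_{model}"] = float(np.sqrt(np.mean(
                (grp[f"G0_{model}"] - grp[f"G0_{reference}"]) ** 2)))
            row[f"RMSE_lE_{model}"] = float(np.sqrt(np.mean(
                (grp[f"lE_{model}"] - grp[f"lE_{reference}"]) ** 2)))
        rows.append(row)
    return pd.DataFrame(rows)
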