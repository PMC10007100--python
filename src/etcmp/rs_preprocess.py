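"""Scene preprocessing: reflectance, albedo, vegetation indices, net radiation.

Turns per-acquisition spectral reflectance bands and a land-surface
temperature raster into the broadband albedo, NDVI/MSAVI, emissivities and
net radiation that the energy-balance stage consumes. All per-pixel
operations accept scalars or numpy arrays interchangeably and propagate NaN
as the missing-value sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from typing import Mapping

import numpy as np

from .constants import ALBEDO_BANDS, ALBEDO_WEIGHTS, STEFAN_BOLTZMANN

log = logging.getLogger(__name__)

__all__ = [
    "SpectralScene",
    "RadiationBudget",
    "toa_reflectance",
    "albedo",
    "ndvi",
    "msavi",
    "emissivity_atmosphere_brunt",
    "net_radiation",
    "radiation_budget",
]


@dataclass
class SpectralScene:
    """One acquisition: shortwave reflectance bands plus surface temperature.

    Parameters
    ----------
    reflectance
        Mapping band name ("B2".."B7") -> reflectance raster in [0, 1].
    surface_temperature
        Land-surface temperature raster [K].
    acquisition_time
        UTC timestamp of the overpass.
    solar_zenith
        Solar zenith angle at the overpass [rad].
    latitude
        Scene-centre latitude [decimal degrees].
    pixel_size
        Ground sampling distance [m].
    """

    reflectance: Mapping[str, np.ndarray]
    surface_temperature: np.ndarray
    acquisition_time: datetime
    solar_zenith: float
    latitude: float
    pixel_size: float = 30.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reflectance = {k: np.asarray(v, dtype=float) for k, v in self.reflectance.items()}
        self.surface_temperature = np.asarray(self.surface_temperature, dtype=float)
        shape = self.surface_temperature.shape
        for name, band in self.reflectance.items():
            if band.shape != shape:
                raise ValueError(
                    f"band {name} shape {band.shape} differs from Ts shape {shape}"
                )
            finite = band[np.isfinite(band)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError(f"band {name} has reflectance outside [0, 1]")
        ts = self.surface_temperature[np.isfinite(self.surface_temperature)]
        if ts.size and ts.min() <= 150.0:
            raise ValueError("surface temperature below 150 K — not in kelvin?")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.surface_temperature.shape

    def band(self, name: str) -> np.ndarray:
        try:
            return self.reflectance[name]
        except KeyError:
            raise KeyError(f"scene is missing band {name}") from None


@dataclass
class RadiationBudget:
    """Derived radiative fields and the scalars that produced them."""

    albedo: np.ndarray
    ndvi: np.ndarray
    msavi: np.ndarray
    emissivity_surface: float
    emissivity_atmosphere: float
    incoming_longwave: float
    solar_radiation: float
    net_radiation: np.ndarray
    air_temperature: float


def toa_reflectance(radiance, sun_earth_distance, band_irradiance, solar_zenith):
    """Planetary reflectance from at-sensor spectral radiance.

    rho = pi * L * d^2 / (K_down * cos(theta_z)); values falling outside
    [0, 1] (sensor/correction artifacts) are clipped and the clip count is
    logged rather than raised.

    Parameters are radiance [W m-2 sr-1 um-1], Sun-Earth distance [AU],
    band exo-atmospheric irradiance [W m-2 um-1], solar zenith [rad].
    """
    solar_zenith = float(solar_zenith)
    if not 0.0 <= solar_zenith < np.pi / 2:
        raise ValueError("sun below horizon: solar zenith must be in [0, pi/2)")
    band_irradiance = np.asarray(band_irradiance, dtype=float)
    if np.any(band_irradiance <= 0):
        raise ValueError("band irradiance must be positive")
    radiance = np.asarray(radiance, dtype=float)
    rho = np.pi * radiance * float(sun_earth_distance) ** 2 / (
        band_irradiance * np.cos(solar_zenith)
    )
    n_clip = int(np.sum((rho < 0) | (rho > 1)))
    if n_clip:
        log.info("toa_reflectance: clipped %d values to [0, 1]", n_clip)
    out = np.clip(rho, 0.0, 1.0)
    return out if out.ndim else float(out)


def albedo(scene_or_bands, weights: Mapping[str, float] | None = None):
    """Broadband shortwave albedo as the weighted sum of band reflectances.

    Accepts either a :class:`SpectralScene` or a mapping band->reflectance.
    ``weights`` defaults to the Landsat-8 B2..B7 weights in
    :data:`etcmp.constants.ALBEDO_WEIGHTS`.
    """
    weights = dict(ALBEDO_WEIGHTS if weights is None else weights)
    bands = scene_or_bands.reflectance if isinstance(scene_or_bands, SpectralScene) else scene_or_bands
    missing = [b for b in weights if b not in bands]
    if missing:
        raise KeyError(f"scene is missing band {missing[0]}")
    total = sum(w * np.asarray(bands[b], dtype=float) for b, w in weights.items())
    return total if np.ndim(total) else float(total)


def ndvi(rho_nir, rho_red):
    """Normalized difference vegetation index (NIR - R)/(NIR + R).

    Pixels with a zero denominator are set to NaN.
    """
    rho_nir = np.asarray(rho_nir, dtype=float)
    rho_red = np.asarray(rho_red, dtype=float)
    denom = rho_nir + rho_red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (rho_nir - rho_red) / denom, np.nan)
    return out if out.ndim else float(out)


def msavi(rho_nir, rho_red):
    """Modified soil-adjusted vegetation index (self-adjusting L form)."""
    rho_nir = np.asarray(rho_nir, dtype=float)
    rho_red = np.asarray(rho_red, dtype=float)
    radicand = (2 * rho_nir + 1) ** 2 - 8 * (rho_nir - rho_red)
    if np.any(radicand < -1e-12):
        raise ValueError("negative radicand in MSAVI — reflectances outside [0, 1]?")
    out = (2 * rho_nir + 1 - np.sqrt(np.maximum(radicand, 0.0))) / 2.0
    out = np.clip(out, -1.0, 1.0)  # roundoff guard at the boundary
    return out if out.ndim else float(out)


def emissivity_atmosphere_brunt(vapor_pressure_kpa: float, air_temperature: float) -> float:
    """Clear-sky atmospheric emissivity, Brunt-type: 1.24 (e_a/T_a)^(1/7).

    ``vapor_pressure_kpa`` is the near-surface vapor pressure [kPa]
    (converted internally to hPa as the formula expects), ``air_temperature``
    in kelvin. Result clipped to [0, 1].
    """
    ea_hpa = 10.0 * float(vapor_pressure_kpa)
    eps = 1.24 * (ea_hpa / float(air_temperature)) ** (1.0 / 7.0)
    return float(np.clip(eps, 0.0, 1.0))


def net_radiation(albedo_, rg, ts, emissivity_surface=0.98, ta=None,
                  emissivity_atmosphere=None, incoming_longwave=None):
    """All-wave net radiation at the surface.

    Rn = (1 - alpha) Rg - sigma eps_s Ts^4 + L_down, with
    L_down = sigma eps_a Ta^4 unless given explicitly.

    Parameters: albedo [0-1], global shortwave Rg [W m-2], surface
    temperature Ts [K], surface emissivity, air temperature Ta [K] and
    atmospheric emissivity (or a precomputed incoming longwave [W m-2]).
    """
    albedo_ = np.asarray(albedo_, dtype=float)
    finite = albedo_[np.isfinite(albedo_)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("albedo outside [0, 1]")
    if float(rg) < 0:
        raise ValueError("Rg must be nonnegative")
    ts = np.asarray(ts, dtype=float)
    if incoming_longwave is None:
        if ta is None or emissivity_atmosphere is None:
            raise ValueError("need (ta, emissivity_atmosphere) or incoming_longwave")
        incoming_longwave = STEFAN_BOLTZMANN * emissivity_atmosphere * float(ta) ** 4
    out = (1.0 - albedo_) * float(rg) - STEFAN_BOLTZMANN * emissivity_surface * ts ** 4 \
        + float(incoming_longwave)
    return out if out.ndim else float(out)


def radiation_budget(scene: SpectralScene, rg: float, ta: float,
                     emissivity_surface: float = 0.98,
                     emissivity_atmosphere: float | None = None,
                     vapor_pressure_kpa: float | None = None) -> RadiationBudget:
    """Full radiative preprocessing of one scene.

    ``rg`` is the global shortwave radiation at overpass time [W m-2] and
    ``ta`` the air temperature [K]. Atmospheric emissivity is taken from
    ``emissivity_atmosphere`` if given, otherwise from the Brunt clear-sky
    formula using ``vapor_pressure_kpa`` (required in that case).
    """
    if emissivity_atmosphere is None:
        if vapor_pressure_kpa is None:
            raise ValueError("need emissivity_atmosphere or vapor_pressure_kpa")
        emissivity_atmosphere = emissivity_atmosphere_brunt(vapor_pressure_kpa, ta)
    alpha = albedo(scene)
    nd = ndvi(scene.band("B5"), scene.band("B4"))
    ms = msavi(scene.band("B5"), scene.band("B4"))
    ldown = STEFAN_BOLTZMANN * emissivity_atmosphere * ta ** 4
    rn = net_radiation(alpha, rg, scene.surface_temperature,
                       emissivity_surface=emissivity_surface,
                       incoming_longwave=ldown)
    return RadiationBudget(
        albedo=alpha, ndvi=nd, msavi=ms,
        emissivity_surface=emissivity_surface,
        emissivity_atmosphere=emissivity_atmosphere,
        incoming_longwave=ldown, solar_radiation=rg,
        net_radiation=rn, air_temperature=ta,
    )
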