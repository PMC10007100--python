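"""FAO-56 reference ET, crop coefficients, and E/T partitioning.

Implements the standardized daily Penman-Monteith reference
evapotranspiration, the single and dual crop-coefficient forms, stagewise
crop-coefficient interpolation, an NDVI->LAI transfer, and the Ritchie
surface-cover split of crop ET into potential transpiration and soil
evaporation that the soil-water simulator uses as its atmospheric boundary
condition.

Daily meteorology is a pandas DataFrame with columns
``date, Ta_mean, Ta_min, Ta_max, Rg, RH_mean, wind_2m`` (Rg in MJ m-2 d-1,
temperatures in deg C, wind at 2 m in m s-1); ``RH_min``/``RH_max`` are used
for the actual vapor pressure when present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "CropCalendar",
    "et0_penman_monteith",
    "extraterrestrial_radiation",
    "saturation_vapor_pressure",
    "kc_interpolate",
    "etc_single",
    "eta_dual",
    "lai_from_ndvi",
    "partition_et",
    "crop_series",
]

#: Solar constant [MJ m-2 min-1]
GSC = 0.0820
#: Stefan-Boltzmann in daily MJ units [MJ K-4 m-2 d-1]
SIGMA_DAILY = 4.903e-9
#: Canopy albedo of the reference grass surface
REF_ALBEDO = 0.23


def saturation_vapor_pressure(t_celsius):
    """Saturation vapor pressure [kPa] at air temperature [deg C]."""
    t = np.asarray(t_celsius, dtype=float)
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return out if out.ndim else float(out)


def extraterrestrial_radiation(latitude_deg: float, day_of_year) -> np.ndarray:
    """Daily extraterrestrial radiation Ra [MJ m-2 d-1]."""
    doy = np.asarray(day_of_year, dtype=float)
    phi = np.radians(latitude_deg)
    dr = 1.0 + 0.033 * np.cos(2 * np.pi / 365 * doy)
    decl = 0.409 * np.sin(2 * np.pi / 365 * doy - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0))
    ra = (24 * 60 / np.pi) * GSC * dr * (
        ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws)
    )
    return ra if ra.ndim else float(ra)


def _actual_vapor_pressure(row) -> float:
    es_min = saturation_vapor_pressure(row["Ta_min"])
    es_max = saturation_vapor_pressure(row["Ta_max"])
    if "RH_max" in row and "RH_min" in row and np.isfinite(row.get("RH_max", np.nan)) \
            and np.isfinite(row.get("RH_min", np.nan)):
        return (es_min * row["RH_max"] / 100.0 + es_max * row["RH_min"] / 100.0) / 2.0
    return (es_min + es_max) / 2.0 * row["RH_mean"] / 100.0


def et0_penman_monteith(meteo: pd.DataFrame, latitude: float,
                        elevation: float = 20.0) -> pd.Series:
    """Daily reference evapotranspiration ET0 [mm d-1].

    Standardized daily Penman-Monteith for the short grass reference:

        ET0 = (0.408 D (Rn - G) + g 900/(T+273) u2 (es - ea))
              / (D + g (1 + 0.34 u2))

    with daily soil heat flux G = 0, net radiation from measured shortwave
    Rg and a clear-sky-indexed longwave term. ``latitude`` in decimal
    degrees, ``elevation`` in m above sea level.
    """
    required = ["date", "Ta_min", "Ta_max", "Rg", "wind_2m"]
    for col in required:
        if col not in meteo.columns:
            raise KeyError(f"meteo table is missing required column {col!r}")
    if "RH_mean" not in meteo.columns and not (
            "RH_min" in meteo.columns and "RH_max" in meteo.columns):
        raise KeyError("meteo table is missing required column 'RH_mean'")
    if np.any(meteo["Ta_min"].to_numpy() > meteo["Ta_max"].to_numpy() + 1e-9):
        raise ValueError("Ta_min exceeds Ta_max")
    if np.any(meteo["wind_2m"].to_numpy() < 0):
        raise ValueError("negative wind speed")

    dates = pd.to_datetime(meteo["date"])
    doy = dates.dt.dayofyear.to_numpy()
    tmin = meteo["Ta_min"].to_numpy(dtype=float)
    tmax = meteo["Ta_max"].to_numpy(dtype=float)
    tmean = meteo["Ta_mean"].to_numpy(dtype=float) if "Ta_mean" in meteo.columns \
        else (tmin + tmax) / 2.0
    rg = meteo["Rg"].to_numpy(dtype=float)
    u2 = meteo["wind_2m"].to_numpy(dtype=float)

    es = (saturation_vapor_pressure(tmin) + saturation_vapor_pressure(tmax)) / 2.0
    ea = np.array([_actual_vapor_pressure(row) for _, row in meteo.iterrows()])
    delta = 4098.0 * saturation_vapor_pressure(tmean) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    ra = extraterrestrial_radiation(latitude, doy)
    rso = (0.75 + 2e-5 * elevation) * np.asarray(ra)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(rso > 0, np.clip(rg / rso, 0.0, 1.0), 0.0)
    rns = (1.0 - REF_ALBEDO) * rg
    rnl = SIGMA_DAILY * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0 \
        * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0))) \
        * np.clip(1.35 * rel - 0.35, 0.0, None)
    rn = rns - rnl

    num = 0.408 * delta * rn + gamma * 900.0 / (tmean + 273.0) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    et0 = np.maximum(num / den, 0.0)
    return pd.Series(et0, index=meteo.index, name="ET0")


# ---------------------------------------------------------------------------
# Crop calendar and coefficients
# ---------------------------------------------------------------------------

@dataclass
class CropCalendar:
    """Season dates, Kc stage values, and an LAI trajectory for one crop.

    ``stage_fractions`` split the season into the four FAO-56 stages
    (initial, development, mid, late) as fractions of the total length;
    ``lai_points`` is a piecewise-linear trajectory of (season fraction,
    LAI) pairs.
    """

    crop: str
    planting: _date
    harvest: _date
    kc_ini: float
    kc_mid: float
    kc_end: float
    stage_fractions: tuple[float, float, float, float] = (0.20, 0.25, 0.35, 0.20)
    lai_points: list[tuple[float, float]] = field(default_factory=list)
    root_depth: float = 0.6  # m

    def __post_init__(self) -> None:
        if self.harvest <= self.planting:
            raise ValueError("harvest must follow planting")
        if min(self.kc_ini, self.kc_mid, self.kc_end) <= 0:
            raise ValueError("Kc values must be positive")
        if abs(sum(self.stage_fractions) - 1.0) > 1e-9:
            raise ValueError("stage fractions must sum to 1")
        if any(lai < 0 for _, lai in self.lai_points):
            raise ValueError("LAI must be nonnegative")

    @property
    def season_days(self) -> int:
        return (self.harvest - self.planting).days + 1

    def season_fraction(self, date) -> float:
        d = pd.Timestamp(date).date()
        if d < self.planting or d > self.harvest:
            raise ValueError(f"{d} outside the {self.crop} season")
        span = (self.harvest - self.planting).days
        return (d - self.planting).days / span if span else 0.0

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.planting, self.harvest, freq="D")

    def lai(self, date) -> float:
        """Piecewise-linear LAI at a date within the season."""
        if not self.lai_points:
            raise ValueError(f"no LAI trajectory configured for {self.crop}")
        f = self.season_fraction(date)
        xs = np.array([p[0] for p in self.lai_points])
        ys = np.array([p[1] for p in self.lai_points])
        return float(np.interp(f, xs, ys))


def kc_interpolate(calendar: CropCalendar, date) -> float:
    """Stagewise FAO-56 crop coefficient at a date.

    Constant ``kc_ini`` over the initial stage, a linear ramp to ``kc_mid``
    over development, constant ``kc_mid`` over mid-season, and a linear ramp
    to ``kc_end`` over the late stage (continuous across breakpoints).
    """
    f = calendar.season_fraction(date)
    f1, f2, f3, _ = calendar.stage_fractions
    b1, b2, b3 = f1, f1 + f2, f1 + f2 + f3
    if f <= b1:
        return float(calendar.kc_ini)
    if f <= b2:
        w = (f - b1) / (b2 - b1)
        return float(calendar.kc_ini + w * (calendar.kc_mid - calendar.kc_ini))
    if f <= b3:
        return float(calendar.kc_mid)
    w = (f - b3) / (1.0 - b3)
    return float(calendar.kc_mid + w * (calendar.kc_end - calendar.kc_mid))


def etc_single(kc, et0):
    """Unstressed crop ET by the single-coefficient form: ETc = Kc ET0."""
    kc = np.asarray(kc, dtype=float)
    et0 = np.asarray(et0, dtype=float)
    if np.any(kc < 0) or np.any(et0 < 0):
        raise ValueError("Kc and ET0 must be nonnegative")
    out = kc * et0
    return out if out.ndim else float(out)


def eta_dual(ks, kcb, ke, et0):
    """Dual-coefficient actual ET: ETa = (Ks Kcb + Ke) ET0.

    ``ks`` in [0, 1] reduces basal transpiration for water/salinity stress.
    """
    ks = np.asarray(ks, dtype=float)
    if np.any(ks < 0) or np.any(ks > 1):
        raise ValueError("Ks must be within [0, 1]")
    out = (ks * np.asarray(kcb, float) + np.asarray(ke, float)) * np.asarray(et0, float)
    return out if out.ndim else float(out)


def lai_from_ndvi(ndvi):
    """Leaf area index from NDVI: LAI = exp(-4.58 + 7.33 NDVI) [m2 m-2]."""
    ndvi = np.asarray(ndvi, dtype=float)
    if np.any(np.abs(ndvi[np.isfinite(ndvi)]) > 1):
        raise ValueError("NDVI outside [-1, 1]")
    out = np.exp(-4.58 + 7.33 * ndvi)
    return out if out.ndim else float(out)


def partition_et(etc, lai):
    """Ritchie split of crop ET into potential transpiration and evaporation.

    SCF = 1 - exp(-0.46 LAI); T_pot = ETc * SCF; E_pot = ETc * (1 - SCF).
    Conserves ETc exactly. Returns (T_pot, E_pot) in the units of ``etc``.
    """
    etc = np.asarray(etc, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(etc < 0) or np.any(lai < 0):
        raise ValueError("ETc and LAI must be nonnegative")
    scf = 1.0 - np.exp(-0.46 * lai)
    t_pot = etc * scf
    e_pot = etc - t_pot
    if t_pot.ndim == 0:
        return float(t_pot), float(e_pot)
    return t_pot, e_pot


def crop_series(calendar: CropCalendar, et0: pd.Series, dates) -> pd.DataFrame:
    """Daily Kc, ETc, LAI, and the E/T split over a season.

    ``et0`` must be indexed alignably with ``dates`` (both daily).
    """
    dates = pd.to_datetime(pd.Index(dates))
    rows = []
    for d, e0 in zip(dates, np.asarray(et0, dtype=float)):
        kc = kc_interpolate(calendar, d)
        etc = etc_single(kc, e0)
        lai = calendar.lai(d) if calendar.lai_points else 0.0
        t_pot, e_pot = partition_et(etc, lai)
        rows.append((d, e0, kc, etc, lai, t_pot, e_pot))
    return pd.DataFrame(
        rows, columns=["date", "ET0", "Kc", "ETc", "LAI", "T_pot", "E_pot"]
    )
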