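"""S-SEBI core: edge fitting, evaporative fraction, soil heat flux, daily ET.

The simplified surface energy balance index partitions available energy
(Rn - G0) between latent and sensible heat using the position of each pixel
between two envelope lines fitted in (albedo, surface temperature) space:
the dry edge T_H(alpha) where all available energy goes to sensible heat
(evaporative fraction 0) and the wet edge T_lambdaE(alpha) where it all goes
to latent heat (evaporative fraction 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import LATENT_HEAT_VAPORIZATION

__all__ = [
    "EdgeModel",
    "EdgeFitConfig",
    "FluxFields",
    "G0_MODELS",
    "fit_edges",
    "evaporative_fraction",
    "soil_heat_flux",
    "partition_energy",
    "latent_to_et_instant",
    "instantaneous_to_daily",
    "daylength",
]

G0_MODELS = ("CLO", "DAU", "BAS", "SOB", "CONST")


@dataclass
class EdgeModel:
    """Dry/wet envelope lines T(alpha) = a + b * alpha.

    ``a_h``/``b_h`` are the dry-edge intercept [K] and slope [K per unit
    albedo]; ``a_le``/``b_le`` the wet edge. ``albedo_domain`` is the albedo
    interval the fit is supported on.
    """

    a_h: float
    b_h: float
    a_le: float
    b_le: float
    albedo_domain: tuple[float, float] = (0.0, 1.0)

    def t_dry(self, alpha):
        return self.a_h + self.b_h * np.asarray(alpha, dtype=float)

    def t_wet(self, alpha):
        return self.a_le + self.b_le * np.asarray(alpha, dtype=float)

    def validate(self) -> None:
        lo, hi = self.albedo_domain
        for a in (lo, hi):
            if self.t_dry(a) <= self.t_wet(a):
                raise ValueError(
                    f"dry edge below wet edge at albedo={a:.3f}: invalid edges"
                )


@dataclass
class EdgeFitConfig:
    """Knobs for the automated envelope fit (see :func:`fit_edges`)."""

    ndvi_mask: float = 0.3          # keep pixels with NDVI >= this
    n_bins: int = 20                # equal-width albedo bins
    pct_lo: float = 2.0             # albedo percentile bounds for binning
    pct_hi: float = 98.0
    dry_percentile: float = 100.0   # per-bin Ts percentile for dry candidates
    wet_percentile: float = 0.0     # per-bin Ts percentile for wet candidates
    min_pixels: int = 200
    min_albedo_range: float = 0.05
    use_inflection: bool = True     # restrict the dry fit to the radiation-
                                    # controlled side (right of the Ts maximum)
    robust_sd: float = 2.0          # residual cutoff for the second pass


def _candidate(alpha, ts, percentile, take_max):
    """Pick the per-bin envelope candidate as an actual pixel.

    With percentile 100 (resp. 0) this is the bin's extreme pixel, whose own
    (alpha, Ts) lies exactly on a noiseless envelope; intermediate
    percentiles pick the pixel at that order statistic, a robustness option
    for heavy-tailed noise.
    """
    if take_max:
        k = int(np.ceil(percentile / 100.0 * len(ts))) - 1
    else:
        k = int(np.floor(percentile / 100.0 * (len(ts) - 1)))
    k = int(np.clip(k, 0, len(ts) - 1))
    order = np.argsort(ts)
    idx = order[k]
    return alpha[idx], ts[idx]


def _fit_line(x, y):
    coeffs = np.polyfit(x, y, 1)
    return float(coeffs[1]), float(coeffs[0])  # intercept, slope


def _robust_refit(x, y, intercept, slope, n_sd):
    resid = y - (intercept + slope * x)
    sd = float(np.std(resid))
    if sd < 1e-9:
        return intercept, slope
    keep = np.abs(resid) <= n_sd * sd
    if keep.sum() >= 2:
        return _fit_line(x[keep], y[keep])
    return intercept, slope


def fit_edges(alpha, ts, ndvi=None, config: EdgeFitConfig | None = None) -> EdgeModel:
    """Fit the dry and wet edges of the (albedo, Ts) scatter.

    Automated replacement for manual edge delineation: vegetated pixels
    (NDVI >= mask threshold) are binned by albedo between the 2nd and 98th
    albedo percentiles; each bin contributes its extreme-Ts pixel as a dry
    (wet) candidate; the dry fit is restricted to bins right of the
    candidate-Ts maximum (the radiation-controlled limb) when
    ``use_inflection`` is set; each line gets one robustness pass dropping
    candidates more than ``robust_sd`` standard deviations from the first
    fit.

    Parameters
    ----------
    alpha, ts, ndvi
        Flat or 2D arrays of albedo [0-1], surface temperature [K], and
        (optionally) NDVI used for masking.
    """
    cfg = config or EdgeFitConfig()
    alpha = np.asarray(alpha, dtype=float).ravel()
    ts = np.asarray(ts, dtype=float).ravel()
    ok = np.isfinite(alpha) & np.isfinite(ts)
    if ndvi is not None:
        nd = np.asarray(ndvi, dtype=float).ravel()
        ok &= np.isfinite(nd) & (nd >= cfg.ndvi_mask)
    alpha, ts = alpha[ok], ts[ok]

    a_lo, a_hi = np.percentile(alpha, [cfg.pct_lo, cfg.pct_hi]) if alpha.size else (0, 0)
    if alpha.size < cfg.min_pixels or (a_hi - a_lo) < cfg.min_albedo_range:
        raise ValueError("scatter insufficient for edge fitting")

    edges = np.linspace(a_lo, a_hi, cfg.n_bins + 1)
    dry_a, dry_t, wet_a, wet_t = [], [], [], []
    for i in range(cfg.n_bins):
        lo, hi = edges[i], edges[i + 1]
        sel = (alpha >= lo) & (alpha <= hi if i == cfg.n_bins - 1 else alpha < hi)
        if sel.sum() < 1:
            continue
        a_bin, t_bin = alpha[sel], ts[sel]
        da, dt = _candidate(a_bin, t_bin, cfg.dry_percentile, take_max=True)
        wa, wt = _candidate(a_bin, t_bin, cfg.wet_percentile, take_max=False)
        dry_a.append(da), dry_t.append(dt)
        wet_a.append(wa), wet_t.append(wt)
    dry_a, dry_t = np.array(dry_a), np.array(dry_t)
    wet_a, wet_t = np.array(wet_a), np.array(wet_t)
    if len(dry_a) < 2:
        raise ValueError("scatter insufficient for edge fitting")

    if cfg.use_inflection:
        i0 = int(np.argmax(dry_t))
        if len(dry_a) - i0 < 2:  # maximum at the right end: use all bins
            i0 = 0
    else:
        i0 = 0
    a_h, b_h = _fit_line(dry_a[i0:], dry_t[i0:])
    a_h, b_h = _robust_refit(dry_a[i0:], dry_t[i0:], a_h, b_h, cfg.robust_sd)
    a_le, b_le = _fit_line(wet_a, wet_t)
    a_le, b_le = _robust_refit(wet_a, wet_t, a_le, b_le, cfg.robust_sd)

    model = EdgeModel(a_h, b_h, a_le, b_le, albedo_domain=(float(a_lo), float(a_hi)))
    model.validate()
    return model


def evaporative_fraction(ts, alpha, edges: EdgeModel, return_clipped_fraction=False):
    """Evaporative fraction Lambda = (T_H(a) - Ts) / (T_H(a) - T_wet(a)).

    0 on the dry edge, 1 on the wet edge; values beyond the envelopes are
    clipped to [0, 1] (they are physical-range violations); the clipped
    fraction is available on request.
    """
    ts = np.asarray(ts, dtype=float)
    th = edges.t_dry(alpha)
    tw = edges.t_wet(alpha)
    if np.any(th <= tw):
        raise ValueError("dry edge at or below wet edge: invalid edges")
    lam = (th - ts) / (th - tw)
    n_fin = np.sum(np.isfinite(lam))
    clipped = float(np.sum((lam < 0) | (lam > 1)) / n_fin) if n_fin else 0.0
    lam = np.clip(lam, 0.0, 1.0)
    lam = lam if lam.ndim else float(lam)
    if return_clipped_fraction:
        return lam, clipped
    return lam


def soil_heat_flux(model_id: str, rn, ts=None, alpha=None, ndvi=None,
                   msavi=None, rho_nir=None, rho_red=None):
    """Soil heat flux G0 as a fraction of net radiation, by model.

    Supported parameterizations (``model_id``):

    - ``CLO``  : G0 = (0.295 - 0.01331 * rhoNIR/rhoR) Rn
    - ``DAU``  : G0 = ((Ts-273.15)/a)(0.032 a + 0.062 a^2)(1 - 0.978 NDVI^4) Rn
    - ``BAS``  : G0 = (Ts-273.15)(0.0038 + 0.074 a)(1 - 0.98 NDVI^4) Rn
    - ``SOB``  : G0 = 0.5 exp(-2.13 MSAVI) Rn
    - ``CONST``: G0 = 0.2 Rn

    Ts is in kelvin (converted internally where the formula uses Celsius).
    Undefined pixels (rhoR=0 for CLO, albedo=0 for DAU) become NaN.
    """
    model_id = model_id.upper()
    rn = np.asarray(rn, dtype=float)
    if model_id == "CONST":
        out = 0.2 * rn
    elif model_id == "CLO":
        rho_nir = np.asarray(rho_nir, dtype=float)
        rho_red = np.asarray(rho_red, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(rho_red > 0, rho_nir / rho_red, np.nan)
        out = (0.295 - 0.01331 * ratio) * rn
    elif model_id == "DAU":
        alpha = np.asarray(alpha, dtype=float)
        tc = np.asarray(ts, dtype=float) - 273.15
        nd = np.asarray(ndvi, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            core = np.where(alpha > 0,
                            tc / alpha * (0.032 * alpha + 0.062 * alpha ** 2),
                            np.nan)
        out = core * (1.0 - 0.978 * nd ** 4) * rn
    elif model_id == "BAS":
        tc = np.asarray(ts, dtype=float) - 273.15
        alpha = np.asarray(alpha, dtype=float)
        nd = np.asarray(ndvi, dtype=float)
        out = tc * (0.0038 + 0.074 * alpha) * (1.0 - 0.98 * nd ** 4) * rn
    elif model_id == "SOB":
        out = 0.5 * np.exp(-2.13 * np.asarray(msavi, dtype=float)) * rn
    else:
        raise ValueError(f"unknown G0 model {model_id!r}; choose from {G0_MODELS}")
    return out if np.ndim(out) else float(out)


def partition_energy(rn, g0, lam):
    """Split available energy: lambdaE = Lambda (Rn - G0); H = the rest.

    Pixels with negative available energy get both fluxes zeroed (and can be
    identified by ``available < 0``); energy closure G0 + H + lambdaE = Rn is
    restored by folding the deficit into H = Rn - G0 - lambdaE exactly.

    Returns (latent, sensible).
    """
    rn = np.asarray(rn, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    lam = np.asarray(lam, dtype=float)
    avail = np.maximum(rn - g0, 0.0)
    le = lam * avail
    h = (rn - g0) - le  # exact closure even where avail was clamped
    if le.ndim == 0:
        return float(le), float(h)
    return le, h


def latent_to_et_instant(le):
    """Instantaneous latent heat flux [W m-2] -> evaporation rate [mm h-1]."""
    le = np.asarray(le, dtype=float)
    if np.any(le[np.isfinite(le)] < 0):
        raise ValueError("latent heat flux must be nonnegative")
    out = le * 3600.0 / LATENT_HEAT_VAPORIZATION
    return out if out.ndim else float(out)


def instantaneous_to_daily(et_i, t, n_daylight):
    """Upscale an instantaneous ET rate to a daily total.

    Assumes the diurnal course of latent heat follows the solar course
    ET(t') = ET_max sin(pi t'/N) between sunrise and sunset, so a single
    observation at t hours after sunrise integrates to
    ET_daily = ET_i * (2 N / pi) / sin(pi t / N)   [mm d-1].
    """
    t = float(t)
    n_daylight = float(n_daylight)
    if not 0.0 < t < n_daylight:
        raise ValueError("overpass outside daylight")
    et_i = np.asarray(et_i, dtype=float)
    out = et_i * (2.0 * n_daylight / np.pi) / np.sin(np.pi * t / n_daylight)
    return out if out.ndim else float(out)


def daylength(latitude: float, day_of_year: int) -> float:
    """Hours between sunrise and sunset from the sunset-hour-angle formula.

    Valid outside the polar circles (|latitude| < 66.5 deg).
    """
    if abs(latitude) >= 66.5:
        raise ValueError("polar latitude: daylength formula not applicable")
    phi = np.radians(latitude)
    decl = 0.409 * np.sin(2.0 * np.pi / 365.0 * day_of_year - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0))
    return float(24.0 / np.pi * ws)


@dataclass
class FluxFields:
    """Per-scene flux rasters from the S-SEBI partition."""

    g0: np.ndarray
    h: np.ndarray
    le: np.ndarray
    lam: np.ndarray
    g0_model_id: str
    clipped_fraction: float = 0.0
    meta: dict = field(default_factory=dict)
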