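"""Root water uptake: Feddes pressure-head stress, osmotic threshold-slope
stress, and the distributed sink term of the flow equation.

The two stresses multiply (no compensation): the local extraction rate is
S_i = alpha_w(h_i) * alpha_os(EC_i) * r_i * T_pot / dz_i where r_i is the
node's share of the normalized root distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CropParams", "feddes_alpha", "osmotic_alpha", "root_distribution", "sink_term"]


@dataclass
class CropParams:
    """Crop rooting and stress parameters.

    Feddes pressure heads (m, negative): ``h1`` (anaerobiosis point, uptake
    zero above), ``h2`` (upper optimal), ``h3_high``/``h3_low`` (lower
    optimal bound at high/low transpirative demand ``t_high``/``t_low`` in
    mm d-1), ``h4`` (wilting point). Osmotic threshold-slope: uptake starts
    declining above pore-water EC ``ec_threshold`` [dS m-1] at
    ``slope_pct`` % per dS m-1.
    """

    name: str
    root_depth: float                 # m
    h1: float
    h2: float
    h3_high: float
    h3_low: float
    h4: float
    ec_threshold: float               # dS m-1
    slope_pct: float                  # % per dS m-1
    t_high: float = 5.0               # mm d-1, demand at which h3 = h3_high
    t_low: float = 1.0
    root_shape: str = "uniform"       # or "linear" (decreasing with depth)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.h1 >= self.h2 >= self.h3_high >= self.h3_low >= self.h4):
            raise ValueError("Feddes heads must satisfy h1>=h2>=h3_high>=h3_low>=h4")
        if self.ec_threshold <= 0 or self.slope_pct < 0:
            raise ValueError("need EC_t > 0 and slope >= 0")
        if self.root_depth <= 0:
            raise ValueError("root depth must be positive")


def _h3(crop: CropParams, t_pot: float) -> float:
    """Demand-dependent lower optimal head (linear between the anchors)."""
    if t_pot >= crop.t_high:
        return crop.h3_high
    if t_pot <= crop.t_low:
        return crop.h3_low
    w = (t_pot - crop.t_low) / (crop.t_high - crop.t_low)
    return crop.h3_low + w * (crop.h3_high - crop.h3_low)


def feddes_alpha(h, crop: CropParams, t_pot: float = 5.0):
    """Piecewise-linear water-stress response alpha(h) in [0, 1].

    Zero above ``h1`` (waterlogging) and below ``h4`` (wilting), one on
    [h3, h2], linear on the ramps; ``h3`` interpolated between
    ``h3_high``/``h3_low`` by the potential transpiration rate [mm d-1].
    """
    h = np.asarray(h, dtype=float)
    h3 = _h3(crop, float(t_pot))
    out = np.zeros_like(h)
    # ramp h4 -> h3
    if h3 > crop.h4:
        ramp = (h - crop.h4) / (h3 - crop.h4)
        out = np.where((h > crop.h4) & (h < h3), ramp, out)
    out = np.where((h >= h3) & (h <= crop.h2), 1.0, out)
    if crop.h1 > crop.h2:
        ramp = (crop.h1 - h) / (crop.h1 - crop.h2)
        out = np.where((h > crop.h2) & (h < crop.h1), ramp, out)
    return out if out.ndim else float(out)


def osmotic_alpha(ec_pore, crop: CropParams):
    """Threshold-slope salinity stress on uptake.

    1 for EC <= EC_t, then declining by ``slope_pct`` percent per dS m-1
    above the threshold, floored at 0.
    """
    ec = np.asarray(ec_pore, dtype=float)
    if np.any(ec < 0):
        raise ValueError("EC must be nonnegative")
    out = np.where(
        ec <= crop.ec_threshold,
        1.0,
        np.maximum(0.0, 1.0 - crop.slope_pct / 100.0 * (ec - crop.ec_threshold)),
    )
    return out if out.ndim else float(out)


def root_distribution(node_depths: np.ndarray, dz: np.ndarray,
                      crop: CropParams) -> np.ndarray:
    """Per-node root fractions summing to 1 over the rooted depth.

    ``node_depths`` are cell-centre depths (m, positive down). "uniform"
    spreads roots evenly over [0, root_depth]; "linear" decreases linearly
    to zero at the root depth.
    """
    d = np.asarray(node_depths, dtype=float)
    dz = np.asarray(dz, dtype=float)
    if crop.root_shape == "uniform":
        w = np.where(d <= crop.root_depth, 1.0, 0.0)
    elif crop.root_shape == "linear":
        w = np.maximum(1.0 - d / crop.root_depth, 0.0)
    else:
        raise ValueError(f"unknown root_shape {crop.root_shape!r}")
    w = w * dz
    total = w.sum()
    if total <= 0:
        raise ValueError("no nodes within the root zone")
    return w / total


def sink_term(h, ec_pore, roots, dz, crop: CropParams, t_pot: float):
    """Distributed uptake rate S per node [d-1] and the actual transpiration.

    S_i = alpha_w(h_i) alpha_os(EC_i) r_i T_pot / dz_i, so the realized
    transpiration sum(S_i dz_i) never exceeds T_pot. ``t_pot`` in mm d-1 is
    converted to m d-1 internally; returns (S [d-1], T_actual [mm d-1]).
    """
    h = np.asarray(h, dtype=float)
    alpha = feddes_alpha(h, crop, t_pot) * osmotic_alpha(ec_pore, crop)
    t_pot_m = float(t_pot) / 1000.0
    s = alpha * np.asarray(roots, float) * t_pot_m / np.asarray(dz, float)
    t_act = float(np.sum(s * dz)) * 1000.0
    return s, t_act
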