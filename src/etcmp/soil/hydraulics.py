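"""van Genuchten-Mualem retention and conductivity on a layered 1D profile.

Units: pressure head h in m (negative = unsaturated), water content theta in
m3 m-3, conductivity K in m d-1, depths in m positive downward for I/O (the
solver converts to an elevation grid internally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SoilLayer", "SoilProfile", "vg_theta", "vg_theta_deriv", "vg_conductivity"]


@dataclass(frozen=True)
class SoilLayer:
    """One homogeneous layer: [z_top, z_bot) depth interval + VG parameters."""

    z_top: float      # m, depth positive down
    z_bot: float
    theta_r: float    # residual water content
    theta_s: float    # saturated water content
    alpha_vg: float   # m-1
    n_vg: float       # > 1
    k_sat: float      # m d-1

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ValueError("need 0 <= theta_r < theta_s <= 1")
        if self.n_vg <= 1.0:
            raise ValueError("van Genuchten n must exceed 1")
        if self.alpha_vg <= 0 or self.k_sat <= 0:
            raise ValueError("alpha_vg and K_sat must be positive")
        if self.z_bot <= self.z_top:
            raise ValueError("layer bottom must be deeper than its top")

    @property
    def m_vg(self) -> float:
        return 1.0 - 1.0 / self.n_vg


@dataclass
class SoilProfile:
    """Ordered, contiguous layers from the surface down."""

    layers: list[SoilLayer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        if abs(self.layers[0].z_top) > 1e-12:
            raise ValueError("first layer must start at the surface (z=0)")
        for upper, lower in zip(self.layers, self.layers[1:]):
            if abs(upper.z_bot - lower.z_top) > 1e-9:
                raise ValueError("layers must be contiguous (no gaps/overlaps)")

    @property
    def depth(self) -> float:
        return self.layers[-1].z_bot

    def layer_at(self, depth: float) -> SoilLayer:
        """Layer containing a depth (m, positive down)."""
        if depth < -1e-12 or depth > self.depth + 1e-12:
            raise ValueError(f"depth {depth} outside profile [0, {self.depth}]")
        for layer in self.layers:
            if depth < layer.z_bot or layer is self.layers[-1]:
                return layer
        return self.layers[-1]

    def layer_index_for_nodes(self, node_depths: np.ndarray) -> np.ndarray:
        bounds = np.array([lyr.z_bot for lyr in self.layers])
        return np.minimum(np.searchsorted(bounds, node_depths, side="right"),
                          len(self.layers) - 1)


def _params(layer_or_arrays):
    if isinstance(layer_or_arrays, SoilLayer):
        l = layer_or_arrays
        return l.theta_r, l.theta_s, l.alpha_vg, l.n_vg, l.m_vg, l.k_sat
    return layer_or_arrays  # tuple of arrays (vectorized path)


def vg_theta(h, layer):
    """Water content from the closed-form retention curve.

    theta(h) = theta_r + (theta_s - theta_r) / (1 + |alpha h|^n)^m for h < 0,
    theta_s for h >= 0, with m = 1 - 1/n.
    """
    tr, ts, a, n, m, _ = _params(layer)
    h = np.asarray(h, dtype=float)
    with np.errstate(over="ignore"):
        se = (1.0 + np.abs(a * np.minimum(h, 0.0)) ** n) ** (-m)
    out = np.where(h >= 0.0, ts, tr + (ts - tr) * se)
    return out if out.ndim else float(out)


def vg_theta_deriv(h, layer):
    """Specific moisture capacity C(h) = d theta / d h [m-1] (0 for h >= 0)."""
    tr, ts, a, n, m, _ = _params(layer)
    h = np.asarray(h, dtype=float)
    ah = np.abs(a * np.minimum(h, 0.0))
    with np.errstate(over="ignore", invalid="ignore"):
        c = (ts - tr) * a * m * n * ah ** (n - 1.0) * (1.0 + ah ** n) ** (-m - 1.0)
    c = np.nan_to_num(c, nan=0.0, posinf=0.0)  # extreme dryness: C -> 0
    out = np.where(h >= 0.0, 0.0, c)
    return out if out.ndim else float(out)


def vg_conductivity(h, layer):
    """Unsaturated conductivity by the Mualem pore-size model.

    K = K_sat Se^0.5 (1 - (1 - Se^(1/m))^m)^2 with
    Se = (theta - theta_r)/(theta_s - theta_r); K(h >= 0) = K_sat.
    """
    tr, ts, a, n, m, ks = _params(layer)
    h = np.asarray(h, dtype=float)
    with np.errstate(over="ignore"):
        se = (1.0 + np.abs(a * np.minimum(h, 0.0)) ** n) ** (-m)
    se = np.clip(se, 1e-12, 1.0)
    k = ks * np.sqrt(se) * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
    out = np.where(h >= 0.0, ks, k)
    return out if out.ndim else float(out)
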