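"""Advection-dispersion transport of pore-water salinity in the column.

Salinity is carried directly as pore-water electrical conductivity
(dS m-1), a linear proxy for salt concentration. Advection is explicit
flux-weighted upwind with internal CFL sub-stepping; hydrodynamic
dispersion (lambda_L |v| + molecular) is Crank-Nicolson implicit. Roots
take up water only, so all salt stays behind.

Boundaries: third-type (Cauchy) at the top - solute enters only with
infiltrating water at the infiltration-water concentration, nothing leaves
with evaporation; zero concentration gradient at the bottom - salt leaves
advectively with drainage only.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

__all__ = ["step_solute"]


def step_solute(c_old: np.ndarray, theta_old: np.ndarray, theta_new: np.ndarray,
                q: np.ndarray, dz: float, dt: float, c_top: float,
                dispersivity: float = 0.05, diffusion: float = 0.0,
                cfl: float = 0.9, top_mode: str = "cauchy"):
    """Advance pore-water concentration one (water-step-aligned) interval.

    Parameters
    ----------
    c_old, theta_old, theta_new
        Nodal concentration [dS m-1] and water content before/after the
        already-taken water step.
    q
        Downward water flux at the n+1 cell interfaces [m d-1], averaged
        over the step (as returned by the flow solver).
    dz, dt
        Cell height [m] and step length [d].
    c_top
        Concentration of infiltrating water [dS m-1].
    dispersivity, diffusion
        Longitudinal dispersivity [m] and molecular diffusion [m2 d-1].
    top_mode
        "cauchy" (default): third-type inlet, solute enters only with the
        advective water flux (the field boundary condition). "concentration":
        first-type inlet at ``c_top``, which also admits a dispersive flux
        across the surface (laboratory column condition).

    Returns (c_new, mass_in, mass_out) with boundary masses in dS m-1 * m
    (concentration x water depth), so a cumulative salt balance can be
    audited externally.
    """
    n = len(c_old)
    q = np.asarray(q, dtype=float)
    if len(q) != n + 1:
        raise ValueError("need n+1 interface fluxes")
    mass = theta_old * np.asarray(c_old, dtype=float)  # per unit area / dz

    # CFL-limited sub-step count for the explicit advection
    theta_face = np.empty(n + 1)
    theta_face[0] = theta_new[0]
    theta_face[1:-1] = 0.5 * (theta_new[:-1] + theta_new[1:])
    theta_face[-1] = theta_new[-1]
    vmax = np.max(np.abs(q) / theta_face)
    n_sub = max(1, int(np.ceil(vmax * dt / (cfl * dz))))
    dts = dt / n_sub

    mass_in = 0.0
    mass_out = 0.0
    flux = np.empty(n + 1)
    for s in range(n_sub):
        # linear-in-time water content for donor concentrations
        w = (s + 0.5) / n_sub
        theta_s = theta_old + w * (theta_new - theta_old)
        c = mass / theta_s

        flux[0] = q[0] * c_top if q[0] > 0 else 0.0
        inner = q[1:-1]
        flux[1:-1] = np.where(inner > 0, inner * c[:-1], inner * c[1:])
        flux[-1] = q[-1] * c[-1] if q[-1] > 0 else 0.0
        mass += dts / dz * (flux[:-1] - flux[1:])
        mass_in += flux[0] * dts
        mass_out += flux[-1] * dts

    # Crank-Nicolson dispersion on concentration; zero dispersive flux at
    # both boundaries for the Cauchy inlet, ghost cell at c_top for the
    # first-type inlet
    c = mass / theta_new
    d_face = dispersivity * np.abs(q[1:-1]) / theta_face[1:-1] + diffusion
    w_face = theta_face[1:-1] * d_face / dz ** 2  # theta*D weights
    d_surf = dispersivity * np.abs(q[0]) / theta_new[0] + diffusion
    w_surf = 2.0 * theta_new[0] * d_surf / dz ** 2 if top_mode == "concentration" else 0.0
    if np.any(w_face > 0) or w_surf > 0:
        # A c = d/dz(theta D dc/dz) discretized; (theta/dt - A/2) c' = (theta/dt + A/2) c
        a_diag = np.zeros(n)
        a_diag[:-1] -= w_face
        a_diag[1:] -= w_face
        a_diag[0] -= w_surf
        a_up = np.zeros(n)
        a_up[:-1] = w_face
        a_lo = np.zeros(n)
        a_lo[1:] = w_face
        rhs = (theta_new / dt + 0.5 * a_diag) * c
        rhs[:-1] += 0.5 * a_up[:-1] * c[1:]
        rhs[1:] += 0.5 * a_lo[1:] * c[:-1]
        rhs[0] += w_surf * c_top
        ab = np.zeros((3, n))
        ab[0, 1:] = -0.5 * a_up[:-1]
        ab[1, :] = theta_new / dt - 0.5 * a_diag
        ab[2, :-1] = -0.5 * a_lo[1:]
        c_new = solve_banded((1, 1), ab, rhs)
        if w_surf > 0:
            mass_in += 0.5 * w_surf * ((c_top - c[0]) + (c_top - c_new[0])) \
                * dz ** 2 / dz * dt
        c = c_new

    return np.maximum(c, 0.0), float(mass_in), float(mass_out)
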