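"""Mass-conservative mixed-form Richards solver on a 1D cell-centered grid.

The column is discretized into uniform cells (default 1 cm) from the
surface down. Each implicit step uses the modified Picard linearization of
the mixed form (water content updated through the retention curve, head as
the primary unknown), which conserves mass to solver tolerance. The
depth-positive-down convention is used throughout this module; the Darcy
flux is positive downward, Q = K (1 - dh/dz).

Boundary conditions:

- top: prescribed flux ("flux"), prescribed head ("head"), or
  "atmospheric" - a net surface flux (rain + irrigation - potential
  evaporation) limited by infiltrability (excess becomes runoff, switching
  to a ponded-head condition) and by a minimum surface pressure head
  ``h_crit`` when evaporating;
- bottom: "free" drainage (unit hydraulic gradient), "flux", or "head".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .hydraulics import SoilProfile, vg_theta, vg_theta_deriv, vg_conductivity

__all__ = ["SolverConfig", "SoilColumn", "SimState", "step_richards",
           "integrate_column", "RichardsNonConvergence"]


class RichardsNonConvergence(RuntimeError):
    """Raised when the Picard iteration fails at the minimum time step."""


@dataclass
class SolverConfig:
    """Numerical knobs for the flow solver."""

    dz: float = 0.01            # m, cell height
    tol_h: float = 1e-5         # m, Picard convergence on max |dh|
    tol_theta: float = 1e-9     # m3 m-3, alternative convergence on max |dtheta|
    tol_wb: float = 1e-6        # m, per-step water-balance increment error
    max_iter: int = 100
    dt_init: float = 1e-3       # d
    dt_min: float = 1e-6
    dt_max: float = 0.05
    dt_grow: float = 1.3        # applied when iterations <= iter_lo
    dt_shrink: float = 0.7      # applied when iterations >= iter_hi
    iter_lo: int = 4
    iter_hi: int = 10
    h_crit: float = -150.0      # m, evaporation-limiting surface head
    h_pond_max: float = 0.0     # m, max ponding before runoff
    internodal: str = "arithmetic"  # or "geometric", "upstream"


class SoilColumn:
    """Discretized profile: per-cell VG parameters and grid geometry."""

    def __init__(self, profile: SoilProfile, config: SolverConfig | None = None):
        self.profile = profile
        self.config = config or SolverConfig()
        dz = self.config.dz
        n = int(round(profile.depth / dz))
        if abs(n * dz - profile.depth) > 1e-9:
            raise ValueError("profile depth must be a multiple of dz")
        self.n = n
        self.dz = dz
        self.depths = (np.arange(n) + 0.5) * dz  # cell centres, positive down
        idx = profile.layer_index_for_nodes(self.depths)
        layers = profile.layers
        self.params = (
            np.array([layers[i].theta_r for i in idx]),
            np.array([layers[i].theta_s for i in idx]),
            np.array([layers[i].alpha_vg for i in idx]),
            np.array([layers[i].n_vg for i in idx]),
            np.array([layers[i].m_vg for i in idx]),
            np.array([layers[i].k_sat for i in idx]),
        )

    def theta(self, h):
        return vg_theta(h, self.params)

    def capacity(self, h):
        return vg_theta_deriv(h, self.params)

    def conductivity(self, h):
        return vg_conductivity(h, self.params)

    def interface_k(self, k_nodes):
        """Internodal conductivity at the n-1 interior interfaces."""
        mode = self.config.internodal
        if mode == "arithmetic":
            return 0.5 * (k_nodes[:-1] + k_nodes[1:])
        if mode == "geometric":
            return np.sqrt(k_nodes[:-1] * k_nodes[1:])
        if mode == "upstream":
            return np.maximum(k_nodes[:-1], k_nodes[1:])
        raise ValueError(f"unknown internodal mode {mode!r}")


@dataclass
class SimState:
    """Nodal state plus cumulative boundary/sink fluxes (all depths in mm)."""

    t: float
    h: np.ndarray
    ec: np.ndarray
    cum: dict = field(default_factory=lambda: {
        "infiltration": 0.0, "runoff": 0.0, "evaporation": 0.0,
        "transpiration": 0.0, "drainage": 0.0,
        "solute_in": 0.0, "solute_out": 0.0,
    })


def _solve_once(col: SoilColumn, h_old, theta_old, dt, top, bottom, sink):
    """One Picard-iterated implicit step at fixed BC modes.

    ``top``/``bottom`` are ("flux", Q) with Q positive downward [m d-1],
    ("head", h) at the respective face, or ("free",) for the bottom.
    Returns (h_new, n_iter, q_top, q_bot) or None if not converged.
    """
    cfg = col.config
    dz, n = col.dz, col.n
    h = h_old.copy()
    s = sink if sink is not None else 0.0
    omega = 1.0          # under-relaxation, reduced if the iteration stalls
    dh_prev = np.inf

    for it in range(1, cfg.max_iter + 1):
        theta_k = col.theta(h)
        cap_k = col.capacity(h)
        k_nodes = col.conductivity(h)
        k_int = col.interface_k(k_nodes)          # interfaces 1..n-1

        # the 1e-12 floor keeps rows of fully dry cells (C ~ 0, K ~ 0)
        # non-singular; its mass contribution is far below solver tolerance
        diag = cap_k / dt + 1e-12
        sub = np.zeros(n)
        sup = np.zeros(n)
        rhs = cap_k / dt * h - (theta_k - theta_old) / dt - s

        # interior interfaces
        diag[:-1] += k_int / dz ** 2
        diag[1:] += k_int / dz ** 2
        sup[:-1] = -k_int / dz ** 2
        sub[1:] = -k_int / dz ** 2
        rhs[:-1] -= k_int / dz          # gravity: -Q_(i+1/2) part
        rhs[1:] += k_int / dz           # gravity: +Q_(i-1/2) part

        # top boundary
        if top[0] == "flux":
            rhs[0] += top[1] / dz
        elif top[0] == "head":
            h_s = top[1]
            k_surf = 0.5 * (float(vg_conductivity(h_s, col.profile.layers[0]))
                            + k_nodes[0])
            diag[0] += 2.0 * k_surf / dz ** 2
            rhs[0] += k_surf / dz + 2.0 * k_surf * h_s / dz ** 2
        else:
            raise ValueError(f"bad top BC {top!r}")

        # bottom boundary
        if bottom[0] == "free":
            rhs[-1] -= k_nodes[-1] / dz
        elif bottom[0] == "flux":
            rhs[-1] -= bottom[1] / dz
        elif bottom[0] == "head":
            h_b = bottom[1]
            k_bot = 0.5 * (float(vg_conductivity(h_b, col.profile.layers[-1]))
                           + k_nodes[-1])
            diag[-1] += 2.0 * k_bot / dz ** 2
            rhs[-1] += -k_bot / dz + 2.0 * k_bot * h_b / dz ** 2
        else:
            raise ValueError(f"bad bottom BC {bottom!r}")

        ab = np.zeros((3, n))
        ab[0, 1:] = sup[:-1]
        ab[1, :] = diag
        ab[2, :-1] = sub[1:]
        h_new = solve_banded((1, 1), ab, rhs)
        # keep iterates physical: overshoot beyond these bounds only ever
        # comes from a wild linearization step
        np.clip(h_new, -1e5, 100.0, out=h_new)

        dh = float(np.max(np.abs(h_new - h)))
        if dh > dh_prev and it > 2:
            # overshoot/cycling (typically nodes near saturation, where the
            # moisture capacity degenerates): damp the update
            omega = max(0.2, omega * 0.6)
        elif dh < 0.5 * dh_prev:
            omega = min(1.0, omega * 1.3)
        dh_prev = dh
        h_prev = h
        h = h + omega * (h_new - h)
        dtheta = float(np.max(np.abs(col.theta(h) - col.theta(h_prev))))
        if dh < cfg.tol_h or dtheta < cfg.tol_theta:
            break
    else:
        return None

    # actual boundary fluxes at the converged state
    k_nodes = col.conductivity(h)
    if top[0] == "flux":
        q_top = top[1]
    else:
        h_s = top[1]
        k_surf = 0.5 * (float(vg_conductivity(h_s, col.profile.layers[0])) + k_nodes[0])
        q_top = k_surf * (1.0 - (h[0] - h_s) / (dz / 2.0))
    if bottom[0] == "free":
        q_bot = k_nodes[-1]
    elif bottom[0] == "flux":
        q_bot = bottom[1]
    else:
        h_b = bottom[1]
        k_bot = 0.5 * (float(vg_conductivity(h_b, col.profile.layers[-1])) + k_nodes[-1])
        q_bot = k_bot * (1.0 - (h_b - h[-1]) / (dz / 2.0))
    return h, it, float(q_top), float(q_bot)


def _interface_fluxes(col: SoilColumn, h, q_top, q_bot):
    """Downward Darcy flux at all n+1 interfaces from the converged heads."""
    k_nodes = col.conductivity(h)
    k_int = col.interface_k(k_nodes)
    q = np.empty(col.n + 1)
    q[0] = q_top
    q[1:-1] = k_int * (1.0 - np.diff(h) / col.dz)
    q[-1] = q_bot
    return q


def step_richards(col: SoilColumn, h_old: np.ndarray, dt: float,
                  top, bottom, sink: np.ndarray | None = None):
    """One implicit flow step with atmospheric BC switching.

    ``top`` may additionally be ("atmospheric", q_net) where ``q_net`` is
    the net potential surface flux (positive down, m d-1). Returns a dict
    with ``h``, per-interface fluxes ``q`` [m d-1 positive down],
    ``q_top``/``q_bot`` actual boundary fluxes, ``runoff`` [m d-1],
    ``iterations``, and the step mass-balance error ``wb_error`` [m].

    Raises :class:`RichardsNonConvergence` when the Picard loop fails (the
    caller is expected to retry at a smaller dt down to ``dt_min``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cfg = col.config
    theta_old = col.theta(h_old)
    runoff_rate = 0.0

    if top[0] == "atmospheric":
        q_net = float(top[1])
        res = _solve_once(col, h_old, theta_old, dt, ("flux", q_net), bottom, sink)
        if q_net > 0 and (res is None or res[0][0] > cfg.h_pond_max):
            # supply exceeds infiltrability (ponding, or the flux-mode solve
            # diverged outright): impose ponded head, excess becomes runoff
            res2 = _solve_once(col, h_old, theta_old, dt,
                               ("head", cfg.h_pond_max), bottom, sink)
            if res2 is not None and res2[2] < q_net:
                res = res2
                runoff_rate = q_net - res[2]
        elif q_net < 0 and (res is None or res[0][0] < cfg.h_crit):
            res2 = _solve_once(col, h_old, theta_old, dt,
                               ("head", cfg.h_crit), bottom, sink)
            if res2 is not None:
                # evaporation cannot exceed potential nor reverse sign
                if res2[2] < q_net:
                    res2 = _solve_once(col, h_old, theta_old, dt,
                                       ("flux", q_net), bottom, sink)
                res = res2
    else:
        res = _solve_once(col, h_old, theta_old, dt, top, bottom, sink)

    if res is None:
        raise RichardsNonConvergence(
            f"Picard iteration failed (dt={dt:g} d, max_iter={cfg.max_iter})")
    h_new, iters, q_top, q_bot = res

    theta_new = col.theta(h_new)
    sink_sum = float(np.sum(sink) * col.dz) if sink is not None else 0.0
    wb_error = float(np.sum(theta_new - theta_old) * col.dz
                     - (q_top - q_bot) * dt + sink_sum * dt)
    return {
        "h": h_new,
        "theta": theta_new,
        "q": _interface_fluxes(col, h_new, q_top, q_bot),
        "q_top": q_top,
        "q_bot": q_bot,
        "runoff": runoff_rate,
        "iterations": iters,
        "wb_error": wb_error,
    }


def integrate_column(col: SoilColumn, h: np.ndarray, duration: float,
                     top, bottom, sink: np.ndarray | None = None,
                     dt_init: float | None = None):
    """Integrate the column over ``duration`` days with adaptive stepping.

    Convenience wrapper around :func:`step_richards` (fixed BCs throughout):
    grows/shrinks dt by iteration count, retries failed steps at smaller dt.
    Returns (h, totals) where totals accumulates time-integrated boundary
    fluxes [m], runoff [m], and the summed |water-balance error| [m].
    """
    cfg = col.config
    t = 0.0
    dt = dt_init if dt_init is not None else cfg.dt_init
    totals = {"q_top": 0.0, "q_bot": 0.0, "runoff": 0.0, "wb_err": 0.0,
              "n_steps": 0}
    last = None
    while t < duration - 1e-12:
        dt = min(dt, duration - t)
        try:
            out = step_richards(col, h, dt, top, bottom, sink)
        except RichardsNonConvergence:
            if dt <= cfg.dt_min * (1 + 1e-9):
                raise
            dt = max(dt * 0.3, cfg.dt_min)
            continue
        h = out["h"]
        totals["q_top"] += out["q_top"] * dt
        totals["q_bot"] += out["q_bot"] * dt
        totals["runoff"] += out["runoff"] * dt
        totals["wb_err"] += abs(out["wb_error"])
        totals["n_steps"] += 1
        t += dt
        last = out
        if out["iterations"] <= cfg.iter_lo:
            dt = min(dt * cfg.dt_grow, cfg.dt_max)
        elif out["iterations"] >= cfg.iter_hi:
            dt = max(dt * cfg.dt_shrink, cfg.dt_min)
    totals["last"] = last
    return h, totals
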