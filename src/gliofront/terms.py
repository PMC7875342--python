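"""Pointwise evaluation of every flux and reaction term of the model.

The model couples five species along a 1D transect through the invasion
front (tumor bulk on the left, healthy tissue on the right):

* tumor density ``N`` moves by flux-saturated (flux-limited) diffusion with
  bounded speed, plus saturated chemotaxis up the MMP1 gradient and
  saturated haptotaxis up the active-integrin gradient, and grows
  logistically;
* MMP1 ``P`` is produced on the microtube band at a rate modulated by the
  tumor activity functional F(N), spreads by the same flux-saturated
  mechanism, and is degraded by tumor cells;
* ECM ``E`` is degraded by MMP1 down to a residual basal level inside the
  tumor;
* integrins exchange between an active pool ``A`` (ECM- and
  activity-dependent activation) and an inactive pool ``I`` (inactivation
  inside the support, exocytosis up to saturation K_I), and are transported
  with the migrating cell membranes.

Everything here is pure array arithmetic with no time stepping.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import FieldError, ParameterError
from .grid import Grid1D
from .params import ModelParams
from .regions import Region

log = logging.getLogger(__name__)

__all__ = [
    "activity_functional",
    "flux_saturated",
    "taxis_flux",
    "logistic_growth",
    "mmp_reaction",
    "ecm_rate",
    "integrin_rates",
    "integrin_transport",
    "porosity_velocity",
]


def _piecewise_linear_cumulative(N: np.ndarray, grid: Grid1D, points: np.ndarray) -> np.ndarray:
    """Exact integral of the piecewise-linear interpolant of N from 0 to each point."""
    C = np.concatenate(([0.0], np.cumsum(0.5 * (N[1:] + N[:-1]) * grid.dx)))
    p = np.clip(points, 0.0, grid.b_omega)
    j = np.clip((p / grid.dx).astype(int), 0, grid.n_nodes - 2)
    xi = p - grid.x[j]
    slope = (N[j + 1] - N[j]) / grid.dx
    return C[j] + N[j] * xi + 0.5 * slope * xi**2


def activity_functional(
    N: np.ndarray, h_p: float, eps_F: float, alpha_F: float, grid: Grid1D
) -> np.ndarray:
    """Tumor activity functional F(N) = (N * I_[-h_p, h_p] + eps_F)^(-alpha_F).

    The convolution is the moving integral of N over the window
    [x - h_p, x + h_p], computed exactly for the piecewise-linear
    interpolant of N and truncated at the domain boundaries (no tissue
    exists outside Omega, so no padding).  F is strictly positive and is
    large where the local tumor mass is small — i.e. at the front — which
    is where protease production and integrin activation concentrate.
    """
    if eps_F <= 0:
        raise ParameterError("eps_F must be strictly positive")
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise FieldError("tumor density field has negative entries")
    upper = _piecewise_linear_cumulative(N, grid, grid.x + h_p)
    lower = _piecewise_linear_cumulative(N, grid, grid.x - h_p)
    return (upper - lower + eps_F) ** (-alpha_F)


def flux_saturated(
    u: np.ndarray, du_dx: np.ndarray, nu: float, m: float, v: float
) -> np.ndarray:
    """Flux-limited (bounded-speed) diffusive flux.

    J = nu * u * u_x / sqrt(m^2 + (nu/v)^2 * u_x^2).

    For small gradients this reduces to the porous-medium flux
    (nu/m) * u * u_x; for steep gradients the transport speed saturates,
    |J| <= v * u, which is what produces the sharp, finitely propagating
    invasion profile.
    """
    if m <= 0 or v <= 0:
        raise ParameterError("m and v must be strictly positive")
    u = np.asarray(u, dtype=float)
    du_dx = np.asarray(du_dx, dtype=float)
    return nu * u * du_dx / np.sqrt(m**2 + (nu / v) ** 2 * du_dx**2)


def taxis_flux(u: np.ndarray, dg_dx: np.ndarray, a: float) -> np.ndarray:
    """Saturated tactic flux J = a * u * g_x / (1 + g_x^2).

    Used with g = P (chemotaxis, a = a1) and g = A (haptotaxis, a = a2).
    The response peaks at unit gradient (|J| <= a*u/2) and shuts down on
    near-discontinuities.
    """
    u = np.asarray(u, dtype=float)
    dg_dx = np.asarray(dg_dx, dtype=float)
    return a * u * dg_dx / (1.0 + dg_dx**2)


def logistic_growth(N: np.ndarray, a3: float, K_N: float) -> np.ndarray:
    """Logistic proliferation rate a3 * N * (1 - N/K_N)."""
    N = np.asarray(N, dtype=float)
    return a3 * N * (1.0 - N / K_N)


def mmp_reaction(
    P: np.ndarray,
    N: np.ndarray,
    E: np.ndarray,
    F: np.ndarray,
    tm: Region,
    a4: float,
    a5: float,
    grid: Grid1D,
) -> np.ndarray:
    """MMP1 reaction a4*E*F*chi_LTM - a5*P*N.

    Production is gated to the microtube band (where the neoplastic tissue
    contacts healthy tissue) and scaled by ECM availability and the
    activity functional; degradation is proportional to the local tumor
    density, which keeps MMP1 at basal levels inside the bulk.
    """
    # a measure-zero band (support edge at the domain boundary) produces nothing
    chi = np.zeros(grid.n_nodes) if tm.width == 0 else tm.indicator(grid)
    return a4 * np.asarray(E, float) * np.asarray(F, float) * chi - a5 * np.asarray(
        P, float
    ) * np.asarray(N, float)


def ecm_rate(
    E: np.ndarray,
    P: np.ndarray,
    a6: float,
    E_basal: float,
    support: Region,
    grid: Grid1D,
) -> np.ndarray:
    """ECM degradation by MMP1 with a basal floor inside the tumor.

    dE/dt = -a6 * (E - E_floor) * P with E_floor = E_basal inside Sup(N)
    and 0 outside.  This relaxation form never drives E below the residual
    level that remains in the bulk after degradation, and reduces to the
    plain -a6*E*P law when E_basal = 0.
    """
    E_floor = E_basal * support.indicator(grid)
    return -a6 * (np.asarray(E, float) - E_floor) * np.asarray(P, float)


def integrin_rates(
    A: np.ndarray,
    I: np.ndarray,
    E: np.ndarray,
    F: np.ndarray,
    support: Region,
    tm: Region,
    params: ModelParams,
    grid: Grid1D,
) -> tuple[np.ndarray, np.ndarray]:
    """Reaction rates (dA, dI) of the active/inactive integrin exchange.

    dA = a7*E*I*F - a8*A*chi_Sup
    dI = -a7*E*I*F + a8*A*chi_Sup + a9*(K_I - A - I)*chi_union

    where chi_union indicates Sup(N) ∪ L_TM (the two share only the point
    b_N, so the union avoids double-counting the exocytosis source there).
    The exchange terms cancel exactly: dA + dI equals the exocytosis term
    alone.
    """
    A = np.asarray(A, float)
    I = np.asarray(I, float)
    chi_sup = support.indicator(grid)
    chi_union = support.union(tm).indicator(grid)
    exchange = params.a7 * np.asarray(E, float) * I * np.asarray(F, float) - params.a8 * A * chi_sup
    exo = params.a9 * (params.K_I - A - I) * chi_union
    return exchange, -exchange + exo


def integrin_transport(
    field: np.ndarray,
    v_Int: float,
    grid: Grid1D,
    direction: str = "toward_front",
) -> np.ndarray:
    """Advective rate of the integrin transport term, first-order upwinded.

    direction="toward_front" carries profiles with the migrating cells in
    +x (rate = -v_Int * df/dx, backward-differenced); "as_printed" is the
    literal +v_Int * df/dx (forward-differenced), which advects in -x.
    The inflow boundary uses a zero-gradient value so constant profiles are
    exact steady states.
    """
    if v_Int < 0:
        raise ParameterError("v_Int must be nonnegative")
    f = np.asarray(field, dtype=float)
    rate = np.zeros_like(f)
    if v_Int == 0.0:
        return rate
    if direction == "toward_front":
        rate[1:] = -v_Int * (f[1:] - f[:-1]) / grid.dx
    elif direction == "as_printed":
        rate[:-1] = v_Int * (f[1:] - f[:-1]) / grid.dx
    else:
        raise ParameterError(f"unknown transport direction {direction!r}")
    return rate


def porosity_velocity(
    E: np.ndarray,
    E0: float,
    eps_min: float,
    eps_max: float,
    v_min: float,
    v_max: float,
) -> np.ndarray:
    """Map ECM density to porosity and porosity to tumor saturation speed.

    Porosity eps(x) = eps_min + (eps_max - eps_min) * (1 - E/E0), clipped
    to [eps_min, eps_max]: intact ECM gives the minimum porosity, full
    degradation the maximum.  The speed ramps smoothly (cubic smoothstep)
    from v_min at eps_min to v_max at eps_max and is constant outside that
    band.  Defaults place the minimum at 50% porosity and the maximum at
    66%.
    """
    if not (0 <= eps_min < eps_max <= 1):
        raise ParameterError("need 0 <= eps_min < eps_max <= 1")
    if E0 <= 0:
        raise ParameterError("E0 must be positive")
    E = np.asarray(E, dtype=float)
    if np.any(E > E0 * (1 + 1e-12)):
        log.warning("ECM exceeds the reference level E0 at %d nodes; clipping", int(np.sum(E > E0)))
    eps = eps_min + (eps_max - eps_min) * (1.0 - np.clip(E, 0.0, E0) / E0)
    s = np.clip((eps - eps_min) / (eps_max - eps_min), 0.0, 1.0)
    ramp = s * s * (3.0 - 2.0 * s)
    return v_min + (v_max - v_min) * ramp
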