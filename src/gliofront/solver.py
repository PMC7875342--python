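"""Time integration of the coupled invasion-front system.

Spatial discretization is a mass-lumped linear-element Galerkin scheme on
the uniform grid, algebraically identical to a conservative finite-volume
stencil: fluxes live on the faces between nodes and the two domain
boundaries carry zero flux, so the discrete totals of N and P are conserved
exactly in the absence of reactions.

Time stepping is IMEX.  For the tumor and protease equations the nonlinear
mobilities of the flux-saturated and tactic fluxes are frozen at the
current state (optionally refreshed by Picard iteration) and the resulting
linear transport operator is inverted implicitly — one tridiagonal solve
per species per step, unconditionally positivity-preserving because the
system matrix is an M-matrix.  Logistic growth is applied by its exact
solution map (operator splitting), linear MMP1 degradation is folded into
the implicit solve.  ECM and the two integrin pools are advanced with
classical RK4, with the transport term first-order upwinded inside the
right-hand side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.linalg.lapack import dgtsv as _dgtsv

from .errors import ParameterError, SolverError
from .grid import Grid1D
from .params import ModelParams
from .regions import Region, tm_region, tumor_support
from .state import FIELD_NAMES, State, Trajectory
from .terms import activity_functional, integrin_transport, porosity_velocity

log = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "StabilityReport",
    "divergence",
    "step_tumor",
    "step_mmp",
    "step_others",
    "simulate",
    "check_stability",
]


class SolverConfig(BaseModel):
    """Time-stepping configuration.

    The default dt gives 1e5 steps over the 15 h horizon — the desk-scale
    resolution; finer production resolutions are a configuration choice.
    """

    model_config = ConfigDict(extra="forbid")

    dt: float = Field(1.5e-4, gt=0, description="time step [h]")
    t_end: float = Field(15.0, gt=0, description="simulation horizon [h]")
    output_times: list[float] = Field(default_factory=lambda: [0.0, 5.0, 10.0, 15.0])
    theta_implicit: float = Field(
        1.0, ge=0.0, le=1.0, description="implicitness of the N and P transport steps"
    )
    cfl_safety: float = Field(0.9, gt=0.0, le=1.0)
    picard_iters: int = Field(1, ge=1, description="frozen-mobility refreshes per implicit solve")
    tol: float = Field(1e-10, gt=0, description="Picard early-exit tolerance")

    @model_validator(mode="after")
    def _check(self) -> "SolverConfig":
        ts = self.output_times
        if sorted(ts) != ts:
            raise ValueError("output_times must be sorted")
        if ts and (ts[0] < 0 or ts[-1] > self.t_end + 1e-12):
            raise ValueError("output_times must lie within [0, t_end]")
        return self


# ---------------------------------------------------------------------------
# conservative plumbing
# ---------------------------------------------------------------------------

def divergence(flux_at_faces: np.ndarray, grid: Grid1D) -> np.ndarray:
    """Node rates -dJ/dx from face fluxes; boundary faces must be zero.

    ``flux_at_faces`` has length n_nodes + 1: entry 0 and entry -1 are the
    domain-boundary faces (no-flux contract), entries 1..n-1 the interior
    faces.  The returned rates telescope: their plain sum is exactly zero.
    """
    J = np.asarray(flux_at_faces, dtype=float)
    if J.shape != (grid.n_nodes + 1,):
        raise SolverError(
            f"face flux has shape {J.shape}, expected ({grid.n_nodes + 1},)"
        )
    if J[0] != 0.0 or J[-1] != 0.0:
        raise SolverError("boundary faces must carry zero flux (no-flux contract)")
    return -np.diff(J) / grid.dx


# ---------------------------------------------------------------------------
# implicit transport kernels (tumor and protease)
# ---------------------------------------------------------------------------

def _fs_mobility(u: np.ndarray, nu: float, m: float, v_face, dx: float) -> np.ndarray:
    """Frozen flux-saturated mobility on faces: D = nu*u_face/sqrt(m^2+(nu/v)^2 s^2)."""
    s = np.diff(u) / dx
    u_face = 0.5 * (u[1:] + u[:-1])
    return nu * u_face / np.sqrt(m * m + (nu / v_face) ** 2 * s * s)


def _taxis_face_velocity(P: np.ndarray, A: np.ndarray, p: ModelParams, dx: float) -> np.ndarray:
    """Frozen tactic drift on faces: a1*sP/(1+sP^2) + a2*sA/(1+sA^2)."""
    sP = np.diff(P) / dx
    sA = np.diff(A) / dx
    return p.a1 * sP / (1.0 + sP * sP) + p.a2 * sA / (1.0 + sA * sA)


def _transport_rate(u, D, w, dx):
    """Explicit conservative rate -dJ/dx for diffusion D and face drift w."""
    wp = np.maximum(w, 0.0)
    wm = np.minimum(w, 0.0)
    J = -D * np.diff(u) / dx + wp * u[:-1] + wm * u[1:]
    rate = np.empty_like(u)
    rate[0] = -J[0] / dx
    rate[-1] = J[-1] / dx
    rate[1:-1] = -np.diff(J) / dx
    return rate


def _implicit_transport_solve(u, D, w, dt, dx, theta, sink=None, src=None):
    """One theta-implicit step of du/dt = d/dx(D du/dx) - d/dx(w u) - sink*u + src.

    Upwind advection and centred diffusion assembled in conservative form;
    the tridiagonal matrix is an M-matrix, so nonnegative data yield a
    nonnegative solution and column sums vanish (exact mass conservation
    for the transport part under no-flux boundaries).
    """
    n = u.shape[0]
    wp = np.maximum(w, 0.0)
    wm = np.minimum(w, 0.0)
    r = dt * theta / (dx * dx)
    q = dt * theta / dx

    diag = np.ones(n)
    diag[:-1] += r * D + q * wp
    diag[1:] += r * D - q * wm
    upper = np.zeros(n)
    upper[1:] = -r * D + q * wm
    lower = np.zeros(n)
    lower[:-1] = -r * D - q * wp
    if sink is not None:
        diag = diag + dt * sink

    rhs = u.copy()
    if theta < 1.0:
        rhs += dt * (1.0 - theta) * _transport_rate(u, D, w, dx)
    if src is not None:
        rhs += dt * src

    # direct LAPACK tridiagonal solve (dgtsv); sub/super-diagonals in its layout
    _, _, _, x, info = _dgtsv(lower[:-1], diag, upper[1:], rhs)
    if info != 0:
        raise SolverError(f"singular tridiagonal system (dgtsv info={info})")
    return x


def _step_tumor_kernel(N, P, A, E, p: ModelParams, cfg: SolverConfig, dt, dx):
    if p.reduced_model:
        w = np.zeros(N.shape[0] - 1)
    else:
        w = _taxis_face_velocity(P, A, p, dx)
    if p.porosity is not None:
        pm = p.porosity
        v_field = porosity_velocity(E, pm.E0, pm.eps_min, pm.eps_max, pm.v_min, pm.v_max)
        v_face = 0.5 * (v_field[1:] + v_field[:-1])
    else:
        v_face = p.v_N
    u = N
    for it in range(cfg.picard_iters):
        D = _fs_mobility(u, p.nu_N, p.m_N, v_face, dx)
        u_new = _implicit_transport_solve(N, D, w, dt, dx, cfg.theta_implicit)
        if it > 0 and np.max(np.abs(u_new - u)) <= cfg.tol:
            u = u_new
            break
        u = u_new
    if p.a3 > 0.0 and not p.reduced_model:
        # exact logistic map: positivity- and bound-preserving splitting
        g = math.exp(p.a3 * dt)
        u = p.K_N * u * g / (p.K_N + u * (g - 1.0))
    return np.maximum(u, 0.0)


def _step_mmp_kernel(P, N, E, F, chi_tm, p: ModelParams, cfg: SolverConfig, dt, dx):
    w = np.zeros(P.shape[0] - 1)
    src = p.a4 * E * F * chi_tm
    sink = p.a5 * N
    u = P
    for it in range(cfg.picard_iters):
        D = _fs_mobility(u, p.nu_P, p.m_P, p.v_P, dx)
        u_new = _implicit_transport_solve(P, D, w, dt, dx, cfg.theta_implicit, sink=sink, src=src)
        if it > 0 and np.max(np.abs(u_new - u)) <= cfg.tol:
            u = u_new
            break
        u = u_new
    return np.maximum(u, 0.0)


# ---------------------------------------------------------------------------
# RK4 kernel (ECM and integrins)
# ---------------------------------------------------------------------------

def _step_others_kernel(E, A, I, P, chi_sup, chi_union, F, p: ModelParams, grid, dt):
    E_floor = p.E_basal * chi_sup
    ori = p.transport_orientation

    def rhs(Ec, Ac, Ic):
        dE = -p.a6 * (Ec - E_floor) * P
        exch = p.a7 * Ec * Ic * F - p.a8 * Ac * chi_sup
        exo = p.a9 * (p.K_I - Ac - Ic) * chi_union
        dA = exch + integrin_transport(Ac, p.v_Int, grid, ori)
        dI = -exch + exo + integrin_transport(Ic, p.v_Int, grid, ori)
        return dE, dA, dI

    k1 = rhs(E, A, I)
    k2 = rhs(E + 0.5 * dt * k1[0], A + 0.5 * dt * k1[1], I + 0.5 * dt * k1[2])
    k3 = rhs(E + 0.5 * dt * k2[0], A + 0.5 * dt * k2[1], I + 0.5 * dt * k2[2])
    k4 = rhs(E + dt * k3[0], A + dt * k3[1], I + dt * k3[2])
    out = []
    floored = 0
    for u, a, b, c, d in zip((E, A, I), k1, k2, k3, k4):
        v = u + (dt / 6.0) * (a + 2.0 * b + 2.0 * c + d)
        neg = v < 0.0
        if neg.any():
            floored += int(np.count_nonzero(v < -1e-12))
            v = np.maximum(v, 0.0)
        out.append(v)
    return out[0], out[1], out[2], floored


# ---------------------------------------------------------------------------
# public one-step operations
# ---------------------------------------------------------------------------

def _production_indicator(tm: Region, grid: Grid1D) -> np.ndarray:
    # a measure-zero microtube band (front edge at the wall) produces nothing
    if tm.is_empty or tm.width == 0.0:
        return np.zeros(grid.n_nodes)
    return tm.indicator(grid)


def _regions_and_activity(state: State, p: ModelParams):
    support = tumor_support(state.N, p.delta_N, state.grid)
    tm = tm_region(support, p.h_p, state.grid)
    F = activity_functional(state.N, p.h_p, p.eps_F, p.alpha_F, state.grid)
    return support, tm, F


def step_tumor(state: State, params: ModelParams, cfg: SolverConfig) -> np.ndarray:
    """Advance the tumor density by one dt; returns the new (nonnegative) N."""
    return _step_tumor_kernel(
        state.N, state.P, state.A, state.E, params, cfg, cfg.dt, state.grid.dx
    )


def step_mmp(state: State, params: ModelParams, cfg: SolverConfig) -> np.ndarray:
    """Advance the MMP1 concentration by one dt; returns the new P."""
    support, tm, F = _regions_and_activity(state, params)
    chi_tm = _production_indicator(tm, state.grid)
    return _step_mmp_kernel(
        state.P, state.N, state.E, F, chi_tm, params, cfg, cfg.dt, state.grid.dx
    )


def step_others(
    state: State, params: ModelParams, cfg: SolverConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance ECM and the integrin pools by one RK4 step of length dt."""
    _enforce_cfl(params, cfg, state.grid)
    support, tm, F = _regions_and_activity(state, params)
    chi_sup = support.indicator(state.grid)
    chi_union = support.union(tm).indicator(state.grid)
    E, A, I, _ = _step_others_kernel(
        state.E, state.A, state.I, state.P, chi_sup, chi_union, F, params, state.grid, cfg.dt
    )
    return E, A, I


def _enforce_cfl(params: ModelParams, cfg: SolverConfig, grid: Grid1D) -> None:
    if params.v_Int > 0 and params.v_Int * cfg.dt / grid.dx > cfg.cfl_safety:
        raise SolverError(
            f"advective CFL violated: v_Int*dt/dx = {params.v_Int * cfg.dt / grid.dx:.3g} "
            f"> cfl_safety = {cfg.cfl_safety}"
        )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate(initial: State, params: ModelParams, cfg: SolverConfig) -> Trajectory:
    """Integrate the coupled system and record snapshots at the output times.

    Regions (tumor support, microtube band) and the activity functional are
    refreshed every step from the current tumor field.  The run is fully
    deterministic: identical inputs give bit-identical trajectories.
    """
    grid = initial.grid
    if params.h_p >= grid.b_omega:
        raise ParameterError("h_p must be smaller than the domain length")
    _enforce_cfl(params, cfg, grid)
    initial.validate()

    p = params
    dx = grid.dx
    N, P, E, A, I = (getattr(initial, f).copy() for f in FIELD_NAMES)
    t = float(initial.t)

    outputs = [ot for ot in cfg.output_times if ot >= t - 1e-12]
    states: list[State] = []
    if outputs and abs(outputs[0] - t) <= 1e-12:
        states.append(State(t=t, grid=grid, N=N.copy(), P=P.copy(), E=E.copy(), A=A.copy(), I=I.copy()))
        outputs = outputs[1:]

    masses = {f: [] for f in FIELD_NAMES}
    floor_events = 0
    step_index = 0

    for target in outputs:
        while t < target - 1e-12:
            h = min(cfg.dt, target - t)
            support = tumor_support(N, p.delta_N, grid)
            tm = tm_region(support, p.h_p, grid)
            F = activity_functional(N, p.h_p, p.eps_F, p.alpha_F, grid)
            chi_tm = _production_indicator(tm, grid)
            chi_sup = support.indicator(grid)
            chi_union = np.minimum(chi_sup + chi_tm, 1.0)

            N_new = _step_tumor_kernel(N, P, A, E, p, cfg, h, dx)
            P_new = _step_mmp_kernel(P, N, E, F, chi_tm, p, cfg, h, dx)
            E, A, I, fl = _step_others_kernel(E, A, I, P, chi_sup, chi_union, F, p, grid, h)
            floor_events += fl
            N, P = N_new, P_new
            t += h
            step_index += 1

            m = {f: float(v.sum()) * dx for f, v in zip(FIELD_NAMES, (N, P, E, A, I))}
            for f, v in m.items():
                masses[f].append(v)
                if not math.isfinite(v):
                    raise SolverError(
                        f"non-finite value in field {f} at step {step_index} (t={t:.6g} h)"
                    )
        t = target  # land exactly on the requested output time
        states.append(State(t=t, grid=grid, N=N.copy(), P=P.copy(), E=E.copy(), A=A.copy(), I=I.copy()))

    if floor_events:
        log.warning("negativity flooring applied at %d node-steps", floor_events)
    diagnostics = {
        "steps": step_index,
        "floor_events": floor_events,
        "mass": {f: np.asarray(v) for f, v in masses.items()},
    }
    return Trajectory(states=states, params=params, solver=cfg, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# stability advisory
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    dt: float
    dx: float
    limits: dict = dc_field(default_factory=dict)
    passed: bool = True
    notes: list = dc_field(default_factory=list)


def check_stability(params: ModelParams, cfg: SolverConfig, grid: Grid1D) -> StabilityReport:
    """Advisory CFL limits and a hard pass/fail on the explicit advection.

    The integrin transport is the only explicitly advanced advection, so
    its CFL limit is binding; the saturation speeds v_N and v_P bound the
    physical signal speed and are reported as accuracy advisories for the
    implicit steps.
    """
    rep = StabilityReport(dt=cfg.dt, dx=grid.dx)
    for name, v in (("v_Int", params.v_Int), ("v_N", params.v_N), ("v_P", params.v_P)):
        rep.limits[name] = math.inf if v == 0 else cfg.cfl_safety * grid.dx / v
    rep.limits["picard_iters"] = cfg.picard_iters
    if cfg.dt > rep.limits["v_Int"]:
        rep.passed = False
        rep.notes.append(
            f"dt={cfg.dt:g} exceeds the advective limit {rep.limits['v_Int']:g} for v_Int"
        )
    for name in ("v_N", "v_P"):
        if cfg.dt > rep.limits[name]:
            rep.notes.append(f"dt exceeds the accuracy advisory for {name} (implicit step)")
    return rep
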