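"""Initial states and scenario variants.

The baseline scenario places the tumor bulk on the left of the transect
with a sharp shoulder; variants enable the porosity-dependent propagation
speed and the chemosensitivity sweep that demonstrates front splitting.
Migration is toward +x everywhere in the package.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigError
from .grid import Grid1D
from .params import ModelParams, PorosityMap
from .regions import tm_region, tumor_support
from .solver import SolverConfig, simulate
from .state import State, Trajectory

import numpy as np

__all__ = [
    "ScenarioSpec",
    "baseline_initial",
    "porosity_variant",
    "chemosensitivity_sweep",
    "preset",
    "PRESETS",
    "SPLITTING_A1",
    "SPLITTING_TIME",
]

# The shipped front-splitting demonstration, calibrated once via the
# chemosensitivity sweep: protease production/turnover is raised so that
# MMP1 (and hence the chemotactic pull) is concentrated at the front, and
# at the high sensitivity the shoulder detaches from the bulk into a
# second mass.  At the low (baseline) sensitivity the same configuration
# keeps a single connected front throughout.
SPLITTING_A1 = 0.2
SPLITTING_TIME = 3.0
SPLITTING_BASE = {"a4": 1.0, "a5": 4.0}


class ScenarioSpec(BaseModel):
    """Declarative description of one simulated experiment."""

    model_config = ConfigDict(extra="forbid")

    name: str = "baseline"
    bulk_extent: float = Field(0.4, gt=0, description="initial tumor bulk length [domain units]")
    shoulder_width: float = Field(0.005, gt=0, description="front shoulder width [domain units]")
    mmp_basal_ratio: float = Field(0.2, ge=0, description="initial P as a fraction of N")
    porosity_velocity: bool = False
    reduced_model: bool = False
    sweep_param: str | None = None
    sweep_values: list[float] = Field(default_factory=list)
    seed: int = 0


def baseline_initial(spec: ScenarioSpec, params: ModelParams, grid: Grid1D) -> State:
    """Construct the initial state: bulk tumor on the left, healthy tissue right.

    N is a plateau at carrying capacity with a tanh shoulder of physical
    width ``shoulder_width`` at ``bulk_extent`` (grid-independent, so runs
    at different resolutions discretize the same profile); ECM sits at the
    healthy level E0 outside the tumor and at the residual E_basal inside;
    MMP1 starts at its basal bulk ratio to N; active integrins at their
    basal bulk level, inactive integrins near saturation inside the bulk
    and at their basal level on the microtube band (nothing ahead of it —
    integrins ride on cell membranes).
    """
    if spec.bulk_extent >= grid.b_omega:
        raise ConfigError("bulk_extent must be smaller than the domain length b_omega")
    x = grid.x
    w = spec.shoulder_width
    shape = 0.5 * (1.0 - np.tanh((x - spec.bulk_extent) / w))  # 1 in bulk, 0 ahead
    N = params.K_N * shape
    E = params.E_basal * shape + params.E0 * (1.0 - shape)
    P = spec.mmp_basal_ratio * N
    A = params.A_basal * shape
    I = (params.K_I - params.A_basal) * shape
    support = tumor_support(N, params.delta_N, grid)
    if not support.is_empty:
        tm = tm_region(support, params.h_p, grid)
        chi_tm = tm.indicator(grid)
        I = np.maximum(I, params.I_basal * chi_tm)
    return State(t=0.0, grid=grid, N=N, P=P, E=E, A=A, I=I)


def porosity_variant(spec: ScenarioSpec, params: ModelParams) -> ModelParams:
    """Enable the porosity-dependent tumor speed v_N(eps).

    The returned parameters carry a PorosityMap anchored at the current
    v_N (minimum speed, at 50% porosity) with a 60% faster maximum at 66%
    porosity, and — when the spec asks for it — the reduced tumor equation
    containing only the flux-saturated term, which isolates the effect of
    the speed map on the front profile.
    """
    update: dict = {
        "porosity": PorosityMap(
            E0=params.E0, v_min=params.v_N, v_max=1.6 * params.v_N
        )
    }
    if spec.reduced_model:
        update["reduced_model"] = True
    return params.model_copy(update=update)


def chemosensitivity_sweep(
    spec: ScenarioSpec,
    params: ModelParams,
    cfg: SolverConfig,
    grid: Grid1D,
    values: list[float],
) -> list[Trajectory]:
    """Run the baseline scenario for each chemotactic sensitivity a1.

    All other settings are held fixed; trajectories are returned in input
    order.  Solver failures propagate tagged with the offending value.
    """
    if any(v < 0 for v in values):
        raise ConfigError("chemotactic sensitivities must be nonnegative")
    out: list[Trajectory] = []
    for v in values:
        p = params.model_copy(update={"a1": float(v)})
        initial = baseline_initial(spec, p, grid)
        try:
            out.append(simulate(initial, p, cfg))
        except Exception as exc:
            raise type(exc)(f"sweep point a1={v}: {exc}") from exc
    return out


def preset(name: str) -> tuple[ScenarioSpec, ModelParams, SolverConfig]:
    """Shipped named scenarios: baseline, porosity, splitting."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return factory()


def _baseline() -> tuple[ScenarioSpec, ModelParams, SolverConfig]:
    return ScenarioSpec(name="baseline"), ModelParams(), SolverConfig()


def _porosity() -> tuple[ScenarioSpec, ModelParams, SolverConfig]:
    spec = ScenarioSpec(name="porosity", porosity_velocity=True, reduced_model=True)
    return spec, porosity_variant(spec, ModelParams()), SolverConfig()


def _splitting() -> tuple[ScenarioSpec, ModelParams, SolverConfig]:
    spec = ScenarioSpec(name="splitting")
    params = ModelParams(a1=SPLITTING_A1, **SPLITTING_BASE)
    cfg = SolverConfig(t_end=SPLITTING_TIME, output_times=[0.0, SPLITTING_TIME])
    return spec, params, cfg


PRESETS = {"baseline": _baseline, "porosity": _porosity, "splitting": _splitting}
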