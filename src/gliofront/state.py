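"""Runtime containers: the five-field state and simulated trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .errors import FieldError
from .grid import Grid1D

if TYPE_CHECKING:  # pragma: no cover
    from .params import ModelParams
    from .solver import SolverConfig

FIELD_NAMES = ("N", "P", "E", "A", "I")

__all__ = ["State", "Trajectory", "FIELD_NAMES"]


@dataclass
class State:
    """The five species sampled on a shared grid at one instant.

    N: tumor density, P: MMP1 concentration, E: ECM density,
    A/I: active/inactive integrins.  All nonnegative.
    """

    t: float
    grid: Grid1D
    N: np.ndarray
    P: np.ndarray
    E: np.ndarray
    A: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        for name in FIELD_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
        self.validate()

    def validate(self) -> None:
        n = self.grid.n_nodes
        for name in FIELD_NAMES:
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise FieldError(f"field {name} has shape {arr.shape}, expected ({n},)")
            if np.any(arr < 0):
                raise FieldError(f"field {name} has negative entries")

    def copy(self) -> "State":
        return State(
            t=self.t,
            grid=self.grid,
            **{name: getattr(self, name).copy() for name in FIELD_NAMES},
        )

    def fields(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in FIELD_NAMES}


@dataclass
class Trajectory:
    """Ordered snapshots of a simulation plus the configuration that made it."""

    states: list[State]
    params: "ModelParams"
    solver: "SolverConfig"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    @property
    def grid(self) -> Grid1D:
        return self.states[0].grid

    def at_time(self, t: float, atol: float = 1e-9) -> State:
        for s in self.states:
            if abs(s.t - t) <= atol:
                return s
        raise KeyError(f"no snapshot at t={t}; have {list(self.times)}")

    def __len__(self) -> int:
        return len(self.states)
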