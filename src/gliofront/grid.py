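"""Uniform 1D spatial mesh on the tissue domain Omega = [0, b_omega]."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["Grid1D"]


@dataclass(frozen=True)
class Grid1D:
    """Uniform node-centred mesh on [0, b_omega].

    Nodes include both endpoints; ``dx = b_omega / (n_nodes - 1)``.  Fluxes
    live on the ``n_nodes - 1`` faces between adjacent nodes; the two domain
    boundaries carry zero flux throughout the package.
    """

    b_omega: float
    n_nodes: int
    x: np.ndarray = field(repr=False, compare=False, default=None)
    dx: float = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.b_omega <= 0:
            raise ParameterError("b_omega must be positive")
        if self.n_nodes < 8:
            raise ParameterError("n_nodes must be at least 8")
        x = np.linspace(0.0, self.b_omega, self.n_nodes)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "dx", float(x[1] - x[0]))

    @classmethod
    def regular(cls, b_omega: float = 1.0, n_nodes: int = 500) -> "Grid1D":
        return cls(b_omega=float(b_omega), n_nodes=int(n_nodes))

    def __len__(self) -> int:
        return self.n_nodes
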