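"""Spatial regions: tumor support Sup(N) and the microtube band L_TM.

The tumor support is the interval [0, b_N] on which the tumor density
exceeds a small detection threshold; the microtube (TM) band is the strip
of width h_p immediately ahead of the support edge, where the cell
protrusions reach into healthy tissue.  Both are represented as unions of
closed intervals with sharp (node-wise) indicator functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FieldError
from .grid import Grid1D

__all__ = ["Region", "tumor_support", "tm_region"]


@dataclass(frozen=True)
class Region:
    """Union of closed, sorted, non-overlapping intervals within Omega."""

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for lo, hi in self.intervals:
            if hi < lo:
                raise ValueError(f"degenerate interval ({lo}, {hi})")
            if lo < prev_hi:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_hi = hi

    # -- constructors ------------------------------------------------------
    @classmethod
    def empty(cls) -> "Region":
        return cls(())

    @classmethod
    def interval(cls, lo: float, hi: float) -> "Region":
        return cls(((float(lo), float(hi)),))

    # -- queries -----------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return len(self.intervals) == 0

    @property
    def left(self) -> float:
        if self.is_empty:
            raise ValueError("empty region has no left edge")
        return self.intervals[0][0]

    @property
    def right(self) -> float:
        if self.is_empty:
            raise ValueError("empty region has no right edge")
        return self.intervals[-1][1]

    @property
    def width(self) -> float:
        return sum(hi - lo for lo, hi in self.intervals)

    def indicator(self, grid: Grid1D) -> np.ndarray:
        """Characteristic function evaluated sharply on grid nodes."""
        chi = np.zeros(grid.n_nodes)
        for lo, hi in self.intervals:
            chi[(grid.x >= lo) & (grid.x <= hi)] = 1.0
        return chi

    def union(self, other: "Region") -> "Region":
        ivals = sorted(self.intervals + other.intervals)
        merged: list[list[float]] = []
        for lo, hi in ivals:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        return Region(tuple((lo, hi) for lo, hi in merged))


def tumor_support(N: np.ndarray, delta_N: float, grid: Grid1D) -> Region:
    """Detect the tumor support [0, b_N] from the density field.

    ``b_N`` is the rightmost position at which N crosses the detection
    threshold ``delta_N``, located by linear interpolation between the last
    super-threshold node and its right neighbour.  Returns the empty region
    when the field never reaches the threshold.
    """
    N = np.asarray(N, dtype=float)
    if N.shape != (grid.n_nodes,):
        raise FieldError(f"field length {N.shape} does not match grid ({grid.n_nodes},)")
    if np.any(N < 0):
        raise FieldError("tumor density field has negative entries")
    above = N >= delta_N
    if not above.any():
        return Region.empty()
    k = int(np.nonzero(above)[0][-1])
    if k == grid.n_nodes - 1:
        b_N = grid.b_omega
    else:
        # linear interpolation of the delta_N crossing in cell [x_k, x_{k+1}]
        b_N = grid.x[k] + grid.dx * (N[k] - delta_N) / (N[k] - N[k + 1])
    return Region.interval(0.0, min(float(b_N), grid.b_omega))


def tm_region(support: Region, h_p: float, grid: Grid1D) -> Region:
    """Microtube band [b_N, min(b_N + h_p, b_omega)] ahead of the support."""
    if support.is_empty:
        return Region.empty()
    b_N = support.right
    return Region.interval(b_N, min(b_N + h_p, grid.b_omega))
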