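"""Front geometry and pattern metrics.

Quantifies the observables the model is judged on: position and speed of
the tumor front edge, front steepness, per-species peak positions and the
signed shifts between them (the protease peak sits migration-ward of the
tumor membrane-density peak), the active-integrin plateau on the microtube
band, the localization of active/inactive exchange at the support edge,
and the number of disjoint tumor components (front splitting).

Migration is toward +x throughout: "ahead" means larger x.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FieldError, ParameterError
from .grid import Grid1D
from .params import ModelParams
from .regions import tm_region, tumor_support
from .state import State, Trajectory
from .terms import activity_functional

__all__ = [
    "FrontReport",
    "front_report",
    "front_count",
    "front_speed",
    "peak_position",
    "support_edge",
    "reports_table",
    "write_reports",
]


def peak_position(field: np.ndarray, grid: Grid1D) -> float:
    """Location of the field maximum: leftmost argmax, parabolically refined.

    Sub-cell refinement is applied only at interior maxima whose neighbours
    are strictly lower (plateaus keep the leftmost node).
    """
    y = np.asarray(field, dtype=float)
    i = int(np.argmax(y))
    if 0 < i < len(y) - 1 and y[i - 1] < y[i] and y[i + 1] < y[i]:
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        if denom < 0:
            offset = 0.5 * (y[i - 1] - y[i + 1]) / denom
            return float(grid.x[i] + offset * grid.dx)
    return float(grid.x[i])


def support_edge(field: np.ndarray, theta: float, grid: Grid1D) -> float | None:
    """Rightmost theta-crossing of a nonnegative field (None if never above)."""
    region = tumor_support(np.maximum(field, 0.0), theta, grid)
    return None if region.is_empty else region.right


def front_count(N: np.ndarray, theta: float) -> int:
    """Number of maximal contiguous node runs with N > theta."""
    if theta <= 0:
        raise ParameterError("theta must be strictly positive")
    above = np.asarray(N) > theta
    if not above.any():
        return 0
    starts = np.diff(above.astype(int), prepend=0) == 1
    return int(starts.sum())


@dataclass
class FrontReport:
    """Per-snapshot observables of the invasion front."""

    time: float
    b_N: float | None
    front_width: float | None
    peaks: dict
    shifts: dict
    n_components: int
    plateau_cv: float | None
    exchange_peak: float | None
    P_edge: float | None

    def to_row(self) -> dict:
        row = {
            "time": self.time,
            "b_N": self.b_N,
            "front_width": self.front_width,
            "n_components": self.n_components,
            "plateau_cv": self.plateau_cv,
            "exchange_peak": self.exchange_peak,
            "P_edge": self.P_edge,
        }
        row.update({f"peak_{k}": v for k, v in self.peaks.items()})
        row.update({f"shift_{k}": v for k, v in self.shifts.items()})
        return row


def _front_width(N: np.ndarray, grid: Grid1D) -> float | None:
    """Distance over which N falls from 0.9*max to 0.1*max on the front side."""
    peak = float(N.max())
    if peak <= 0:
        return None
    hi = support_edge(N, 0.9 * peak, grid)
    lo = support_edge(N, 0.1 * peak, grid)
    if hi is None or lo is None:
        return None
    return max(lo - hi, 0.0)


def front_report(state: State, params: ModelParams) -> FrontReport:
    """Compute all front observables for one snapshot.

    On an empty tumor (density everywhere below the detection threshold)
    the positional entries are None and no error is raised.
    """
    grid = state.grid
    support = tumor_support(state.N, params.delta_N, grid)
    if support.is_empty:
        return FrontReport(
            time=state.t, b_N=None, front_width=None, peaks={}, shifts={},
            n_components=0, plateau_cv=None, exchange_peak=None, P_edge=None,
        )
    b_N = support.right
    tm = tm_region(support, params.h_p, grid)
    peaks = {name: peak_position(getattr(state, name), grid) for name in ("N", "P", "A", "I")}
    shifts = {
        "P_minus_N": peaks["P"] - peaks["N"],
        "A_minus_N": peaks["A"] - peaks["N"],
        "P_minus_A": peaks["P"] - peaks["A"],
    }

    chi_tm = tm.indicator(grid).astype(bool)
    plateau_cv = None
    if chi_tm.any():
        a_tm = state.A[chi_tm]
        mean = float(a_tm.mean())
        if mean > 0:
            plateau_cv = float((a_tm.max() - a_tm.min()) / mean)

    # active/inactive exchange rate |a7*E*I*F - a8*A*chi_Sup|: its peak marks
    # where the pools trade places, expected at the support/TM boundary
    F = activity_functional(state.N, params.h_p, params.eps_F, params.alpha_F, grid)
    chi_sup = support.indicator(grid)
    exchange = params.a7 * state.E * state.I * F - params.a8 * state.A * chi_sup
    exchange_peak = peak_position(np.abs(exchange), grid)

    P_edge = None
    if state.P.max() > 0:
        P_edge = support_edge(state.P, max(params.delta_N, 1e-3 * float(state.P.max())), grid)

    return FrontReport(
        time=state.t,
        b_N=b_N,
        front_width=_front_width(state.N, grid),
        peaks=peaks,
        shifts=shifts,
        n_components=front_count(state.N, params.delta_N),
        plateau_cv=plateau_cv,
        exchange_peak=exchange_peak,
        P_edge=P_edge,
    )


def front_speed(trajectory: Trajectory) -> np.ndarray:
    """Front-edge displacement rate db_N/dt over the output times.

    Centered finite differences (one-sided at the ends).  In any valid run
    every entry is bounded by the tumor saturation speed v_N (within a few
    percent of front-detection jitter).
    """
    if len(trajectory) < 2:
        raise FieldError("front_speed needs at least two snapshots")
    p = trajectory.params
    edges = []
    for s in trajectory.states:
        region = tumor_support(s.N, p.delta_N, s.grid)
        edges.append(np.nan if region.is_empty else region.right)
    return np.gradient(np.asarray(edges, dtype=float), trajectory.times)


def reports_table(trajectory: Trajectory) -> pd.DataFrame:
    """One row of front observables per output time, plus the front speed."""
    rows = [front_report(s, trajectory.params).to_row() for s in trajectory.states]
    df = pd.DataFrame(rows)
    if len(trajectory) >= 2:
        df["front_speed"] = front_speed(trajectory)
    return df


def write_reports(trajectory: Trajectory, directory: str | Path) -> tuple[Path, Path]:
    """Serialize the per-time table (CSV) and a structured summary (JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table = reports_table(trajectory)
    csv_path = directory / "front_reports.csv"
    table.to_csv(csv_path, index=False)
    last = front_report(trajectory.states[-1], trajectory.params)
    summary = {
        "final_time": last.time,
        "final_report": asdict(last),
        "max_front_speed": float(np.nanmax(front_speed(trajectory))) if len(trajectory) >= 2 else None,
        "steps": trajectory.diagnostics.get("steps"),
        "floor_events": trajectory.diagnostics.get("floor_events"),
    }
    json_path = directory / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2))
    return csv_path, json_path
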