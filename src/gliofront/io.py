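"""Trajectory serialization: delimited text and an optional HDF5 container."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FieldError
from .grid import Grid1D
from .params import ModelParams
from .solver import SolverConfig
from .state import FIELD_NAMES, State, Trajectory

__all__ = ["write_trajectory", "read_trajectory", "trajectory_frame"]


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format table: one row per (output time, node) with all fields."""
    if len(traj) == 0:
        raise FieldError("empty trajectory")
    blocks = []
    for s in traj.states:
        block = {"t": np.full(s.grid.n_nodes, s.t), "x": s.grid.x}
        block.update(s.fields())
        blocks.append(pd.DataFrame(block))
    return pd.concat(blocks, ignore_index=True)


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "csv") -> Path:
    """Write snapshots as CSV (full repr precision) or a single HDF5 file.

    The text format round-trips values to <= 1e-12 relative; the binary
    container is bit-exact and also stores the parameter and solver
    configuration as JSON attributes.
    """
    if len(traj) == 0:
        raise FieldError("refusing to write an empty trajectory")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        trajectory_frame(traj).to_csv(path, index=False, float_format="%.17g")
    elif format == "h5":
        with h5py.File(path, "w") as f:
            f.attrs["params"] = json.dumps(traj.params.model_dump(mode="json"))
            f.attrs["solver"] = json.dumps(traj.solver.model_dump(mode="json"))
            f.attrs["b_omega"] = traj.grid.b_omega
            f.attrs["n_nodes"] = traj.grid.n_nodes
            f.create_dataset("times", data=traj.times)
            f.create_dataset("x", data=traj.grid.x)
            for name in FIELD_NAMES:
                data = np.stack([getattr(s, name) for s in traj.states])
                f.create_dataset(name, data=data)
    else:
        raise FieldError(f"unknown trajectory format {format!r} (use 'csv' or 'h5')")
    return path


def read_trajectory(
    path: str | Path,
    params: ModelParams | None = None,
    solver: SolverConfig | None = None,
) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    The HDF5 container restores the stored configuration; the CSV format
    carries fields only, so ``params``/``solver`` default to the shipped
    defaults unless supplied.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            params = ModelParams.model_validate(json.loads(f.attrs["params"]))
            solver = SolverConfig.model_validate(json.loads(f.attrs["solver"]))
            grid = Grid1D(b_omega=float(f.attrs["b_omega"]), n_nodes=int(f.attrs["n_nodes"]))
            times = f["times"][:]
            data = {name: f[name][:] for name in FIELD_NAMES}
        states = [
            State(t=float(t), grid=grid, **{n: data[n][k] for n in FIELD_NAMES})
            for k, t in enumerate(times)
        ]
        return Trajectory(states=states, params=params, solver=solver)

    df = pd.read_csv(path)
    missing = {"t", "x", *FIELD_NAMES} - set(df.columns)
    if missing:
        raise FieldError(f"trajectory file lacks columns {sorted(missing)}")
    params = params or ModelParams()
    solver = solver or SolverConfig()
    states = []
    grid = None
    for t, block in df.groupby("t", sort=True):
        if grid is None:
            x = block["x"].to_numpy()
            grid = Grid1D(b_omega=float(x[-1]), n_nodes=len(x))
        states.append(
            State(
                t=float(t),
                grid=grid,
                **{n: block[n].to_numpy(dtype=float) for n in FIELD_NAMES},
            )
        )
    return Trajectory(states=states, params=params, solver=solver)
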