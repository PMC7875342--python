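"""Basic visualisation of snapshots and trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .params import ModelParams
from .regions import tm_region, tumor_support
from .state import State, Trajectory

SPECIES_STYLE = {
    "N": dict(color="tab:red", label="tumor N"),
    "P": dict(color="tab:green", label="MMP1 P"),
    "E": dict(color="tab:gray", label="ECM E"),
    "A": dict(color="tab:blue", label="active integrins A"),
    "I": dict(color="tab:cyan", label="inactive integrins I"),
}


def plot_snapshot(state: State, params: ModelParams, ax=None):
    """All five species along the transect, with the microtube band shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    for name, style in SPECIES_STYLE.items():
        ax.plot(state.grid.x, getattr(state, name), lw=1.2, **style)
    support = tumor_support(state.N, params.delta_N, state.grid)
    if not support.is_empty:
        band = tm_region(support, params.h_p, state.grid)
        ax.axvspan(band.left, band.right, color="red", alpha=0.15, lw=0)
        ax.axvline(support.right, color="k", ls=":", lw=0.8)
    ax.set_xlabel("position x [domain units]")
    ax.set_ylabel("density / concentration")
    ax.set_title(f"t = {state.t:g} h")
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_trajectory(traj: Trajectory, path=None):
    """One panel per stored snapshot; optionally saved to ``path``."""
    n = len(traj)
    fig, axes = plt.subplots(n, 1, figsize=(7, 3.0 * n), squeeze=False)
    for ax, state in zip(axes[:, 0], traj.states):
        plot_snapshot(state, traj.params, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
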