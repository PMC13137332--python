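"""Rendering helpers: colony images, solute heat maps, metric dynamics plots.

Detoxifier cells are drawn in magenta and consumer cells in cyan, the
two-color convention for this consortium.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .engine import Snapshot, Trajectory
from .fields import SOLUTES, SoluteFields
from .metrics import radial_abundance_profile, trajectory_metrics

SPECIES_COLORS = {"detoxifier": "magenta", "consumer": "cyan"}


def plot_colony(snapshot: Snapshot, ax=None, point_size: float = 4.0):
    """Scatter plot of the colony, one dot per cell, colored by species."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cells = snapshot.cells
    for name, color in SPECIES_COLORS.items():
        sub = cells[cells["species"] == name]
        ax.scatter(sub["x"], sub["y"], s=point_size, c=color, label=name, lw=0)
    ax.set_aspect("equal")
    ax.set_xlabel("x (lattice units)")
    ax.set_ylabel("y (lattice units)")
    ax.set_title(f"t = {snapshot.time:.1f} h, n = {len(cells)}")
    ax.legend(frameon=False, markerscale=3)
    return ax


def plot_fields(fields: SoluteFields, axes=None):
    """Heat maps of the three solute lattices."""
    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, name in zip(axes, SOLUTES):
        im = ax.imshow(fields.grid(name), origin="lower", cmap="viridis")
        ax.set_title(f"{name} (C-mM)")
        plt.colorbar(im, ax=ax, shrink=0.8)
    return axes


def plot_radial_profile(snapshot: Snapshot, bin_width: float = 2.0, ax=None):
    """Detoxifier relative abundance vs distance from the colony centroid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    prof = radial_abundance_profile(snapshot, bin_width=bin_width)
    occ = prof.occupied
    ax.plot(prof.bin_centers[occ], prof.detox_fraction[occ], "o-")
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("radius (lattice units)")
    ax.set_ylabel("detoxifier relative abundance")
    return ax


def plot_dynamics(trajectory: Trajectory, ax=None):
    """Frontier detoxifier fraction and growth-rate ratio over time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 3.5))
    table = trajectory_metrics(trajectory)
    ax.plot(table["time"], table["frontier_fraction"], label="frontier detox fraction")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("frontier detoxifier fraction")
    ax2 = ax.twinx()
    ax2.plot(table["time"], table["growth_rate_ratio"], color="C1",
             label="growth-rate ratio")
    ax2.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax2.set_ylabel("detoxifier / consumer growth rate")
    return ax


def save_figure(ax, path, dpi: int = 150):
    fig = np.atleast_1d(ax).ravel()[0].figure
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
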