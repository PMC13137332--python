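"""Agent lifecycle: biomass growth, division, death and overlap relaxation.

Cells are soft discs on the same 2D plane as the solute lattices.  Each cell
carries a species label, position, biomass, and its last realized net growth
rate.  Biomass integrates exponentially (exact for a constant rate over one
step), cells divide symmetrically when they reach twice the birth mass, die
when starvation shrinks them below a fraction of the birth mass, and the
colony expands physically through iterative pairwise shoving of overlapping
discs — the mechanism by which divisions at the growth zone push the frontier
outward.

The population is stored as a structure of arrays for speed; the exported
table (one row per cell) is the snapshot format the spatial metrics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .kinetics import Species

__all__ = [
    "AgentParams",
    "CellPopulation",
    "update_biomass",
    "maybe_divide",
    "relax_overlaps",
    "cull_dead",
]


@dataclass(frozen=True)
class AgentParams:
    """Mechanical and lifecycle constants shared by both strains.

    ``base_radius`` is the disc radius at the birth mass; radius scales as
    sqrt(biomass) so disc area tracks biomass.  A cell divides at exactly
    2x the birth mass and dies when decay shrinks it below
    ``death_fraction`` x birth mass.  ``division_jitter`` adds a small
    uniform perturbation (fraction of the radius) to daughter placement to
    break lattice artifacts.
    """

    birth_mass: float = 1.0
    base_radius: float = 0.35
    death_fraction: float = 0.25
    division_jitter: float = 0.05
    relax_max_iters: int = 20
    relax_tol: float = 0.02
    #: contact inhibition: a cell whose residual disc overlap after the
    #: relaxation step exceeds this fraction of its radius is jammed and
    #: pauses growth until the crowding resolves; 0 disables.  Mimics the
    #: pressure-limited growth of packed colony interiors, confining active
    #: growth to a peripheral layer.
    crowding_threshold: float = 0.12


class CellPopulation:
    """Structure-of-arrays container for the living cells of one colony."""

    def __init__(self, species, x, y, biomass, birth_mass, params: AgentParams,
                 cell_id=None, alive=None, last_growth_rate=None, next_id=None):
        self.species = np.asarray(species, dtype=np.int8)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.biomass = np.asarray(biomass, dtype=float)
        self.birth_mass = np.asarray(birth_mass, dtype=float)
        self.params = params
        n = len(self.x)
        self.cell_id = (
            np.arange(n, dtype=np.int64) if cell_id is None
            else np.asarray(cell_id, dtype=np.int64)
        )
        self.alive = (
            np.ones(n, dtype=bool) if alive is None else np.asarray(alive, dtype=bool)
        )
        self.last_growth_rate = (
            np.zeros(n) if last_growth_rate is None
            else np.asarray(last_growth_rate, dtype=float)
        )
        self.next_id = int(self.cell_id.max()) + 1 if next_id is None and n else (
            next_id if next_id is not None else 0
        )
        if np.any(self.biomass[self.alive] <= 0):
            raise ValueError("alive cells must have positive biomass")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def radius(self) -> np.ndarray:
        """Disc radius, monotone in biomass (area proportional to biomass)."""
        return self.params.base_radius * np.sqrt(
            np.maximum(self.biomass, 0.0) / self.params.birth_mass
        )

    def counts(self) -> dict:
        return {
            "detoxifier": int(np.sum(self.species == Species.DETOXIFIER)),
            "consumer": int(np.sum(self.species == Species.CONSUMER)),
        }

    def to_frame(self) -> pd.DataFrame:
        """Snapshot table: one row per cell, the format the metrics consume."""
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "species": np.where(
                    self.species == Species.DETOXIFIER, "detoxifier", "consumer"
                ),
                "x": self.x,
                "y": self.y,
                "biomass": self.biomass,
                "growth_rate": self.last_growth_rate,
                "alive": self.alive,
            }
        )

    def copy(self) -> "CellPopulation":
        return CellPopulation(
            self.species.copy(), self.x.copy(), self.y.copy(), self.biomass.copy(),
            self.birth_mass.copy(), self.params, self.cell_id.copy(),
            self.alive.copy(), self.last_growth_rate.copy(), self.next_id,
        )


def update_biomass(pop: CellPopulation, g, dt: float) -> CellPopulation:
    """Exponential biomass update m <- m * exp(g*dt); flags starved cells dead.

    Exact for a constant specific rate over the step, so single-cell doubling
    times do not depend on dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = np.broadcast_to(np.asarray(g, dtype=float), pop.biomass.shape)
    pop.biomass = pop.biomass * np.exp(g * dt)
    pop.last_growth_rate = np.array(g, dtype=float)
    starved = pop.biomass < pop.params.death_fraction * pop.birth_mass
    pop.alive &= ~starved
    return pop


def maybe_divide(pop: CellPopulation, rng: np.random.Generator) -> CellPopulation:
    """Split every cell at or above 2x birth mass into two equal daughters.

    Daughters take half the mother's biomass each (conserved exactly) and are
    placed at +/- radius/2 along a uniformly random axis, with a small
    uniform jitter; the overlap relaxation that follows does the pushing.
    """
    mask = pop.alive & (pop.biomass >= 2.0 * pop.birth_mass)
    if not mask.any():
        return pop
    idx = np.nonzero(mask)[0]
    k = len(idx)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=k)
    axis = np.column_stack([np.cos(phi), np.sin(phi)])
    half = pop.biomass[idx] / 2.0
    r_half = pop.params.base_radius * np.sqrt(half / pop.params.birth_mass)
    offset = axis * (r_half / 2.0)[:, None]
    jitter = rng.uniform(-1.0, 1.0, size=(k, 2)) * (
        pop.params.division_jitter * r_half[:, None]
    )

    # mother becomes daughter 1 in place
    pop.biomass[idx] = half
    mx, my = pop.x[idx].copy(), pop.y[idx].copy()
    pop.x[idx] = mx + offset[:, 0] + jitter[:, 0]
    pop.y[idx] = my + offset[:, 1] + jitter[:, 1]

    new_ids = pop.next_id + np.arange(k, dtype=np.int64)
    pop.next_id += k
    pop.species = np.concatenate([pop.species, pop.species[idx]])
    pop.x = np.concatenate([pop.x, mx - offset[:, 0] - jitter[:, 0]])
    pop.y = np.concatenate([pop.y, my - offset[:, 1] - jitter[:, 1]])
    pop.biomass = np.concatenate([pop.biomass, half])
    pop.birth_mass = np.concatenate([pop.birth_mass, pop.birth_mass[idx]])
    pop.cell_id = np.concatenate([pop.cell_id, new_ids])
    pop.alive = np.concatenate([pop.alive, np.ones(k, dtype=bool)])
    pop.last_growth_rate = np.concatenate(
        [pop.last_growth_rate, pop.last_growth_rate[idx]]
    )
    return pop


def residual_overlaps(pop: CellPopulation) -> np.ndarray:
    """Per-cell deepest remaining pairwise overlap (post-relaxation crowding)."""
    n = len(pop)
    out = np.zeros(n)
    if n < 2:
        return out
    pos = pop.positions
    r = pop.radius
    pairs = cKDTree(pos).query_pairs(2.0 * r.max(), output_type="ndarray")
    if len(pairs) == 0:
        return out
    i, j = pairs.T
    dist = np.hypot(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1])
    ov = np.maximum(r[i] + r[j] - dist, 0.0)
    np.maximum.at(out, i, ov)
    np.maximum.at(out, j, ov)
    return out


def max_overlap(pop: CellPopulation) -> float:
    """Largest pairwise disc overlap depth (0 if none); diagnostic for tests."""
    n = len(pop)
    if n < 2:
        return 0.0
    pos = pop.positions
    r = pop.radius
    pairs = cKDTree(pos).query_pairs(2.0 * r.max(), output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    i, j = pairs.T
    dist = np.hypot(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1])
    return float(np.maximum(r[i] + r[j] - dist, 0.0).max())


def relax_overlaps(
    pop: CellPopulation, max_iters: int | None = None, tol: float | None = None,
    return_residuals: bool = False,
):
    """Iterative pairwise soft-disc shoving until overlaps fall below ``tol``.

    Each overlapping pair is displaced half the overlap apart along the
    centre line — displacements are pairwise antisymmetric, so the step
    imparts no net momentum.  Candidate pairs are gathered once per call with
    a 1.3x search margin and reused across iterations (per-iteration motion
    is a fraction of a radius).  Non-convergence within ``max_iters`` is not
    fatal; the residual shrinks on subsequent simulation steps.
    """
    max_iters = pop.params.relax_max_iters if max_iters is None else max_iters
    tol = pop.params.relax_tol if tol is None else tol
    n = len(pop)
    if n < 2:
        return (pop, np.zeros(n)) if return_residuals else pop
    pos = pop.positions
    r = pop.radius
    pairs = cKDTree(pos).query_pairs(2.0 * r.max() * 1.3, output_type="ndarray")
    if len(pairs) == 0:
        return (pop, np.zeros(n)) if return_residuals else pop
    i, j = pairs.T
    sum_r = r[i] + r[j]
    for _ in range(max_iters):
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dist = np.hypot(dx, dy)
        overlap = sum_r - dist
        act = overlap > tol
        if not act.any():
            break
        ai, aj = i[act], j[act]
        d_act = dist[act]
        # coincident centres: push apart along a fixed axis, deterministically
        zero = d_act < 1e-12
        ux = np.where(zero, 1.0, dx[act] / np.where(zero, 1.0, d_act))
        uy = np.where(zero, 0.0, dy[act] / np.where(zero, 1.0, d_act))
        push = 0.5 * overlap[act]
        px, py = ux * push, uy * push
        pos[:, 0] += np.bincount(ai, weights=px, minlength=n)
        pos[:, 0] -= np.bincount(aj, weights=px, minlength=n)
        pos[:, 1] += np.bincount(ai, weights=py, minlength=n)
        pos[:, 1] -= np.bincount(aj, weights=py, minlength=n)
    pop.x = pos[:, 0]
    pop.y = pos[:, 1]
    if not return_residuals:
        return pop
    dist = np.hypot(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1])
    ov = np.maximum(sum_r - dist, 0.0)
    residual = np.zeros(n)
    np.maximum.at(residual, i, ov)
    np.maximum.at(residual, j, ov)
    return pop, residual


def cull_dead(pop: CellPopulation) -> tuple[CellPopulation, int]:
    """Drop cells flagged dead; returns (survivors, number removed)."""
    keep = pop.alive
    n_removed = int((~keep).sum())
    if n_removed == 0:
        return pop, 0
    out = CellPopulation(
        pop.species[keep], pop.x[keep], pop.y[keep], pop.biomass[keep],
        pop.birth_mass[keep], pop.params, pop.cell_id[keep], pop.alive[keep],
        pop.last_growth_rate[keep], pop.next_id,
    )
    return out, n_removed
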