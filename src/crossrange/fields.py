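"""Reaction-diffusion bookkeeping for the three solute lattices (S, I, P).

The simulation shares one 2D lattice layer between cells and solutes: the
substrate S, the intermediate I and the final product P each live on a
node-centred square grid with spacing ``h``.  Diffusion uses an explicit
five-point FTCS scheme with no-flux (reflecting) boundaries, which conserves
total mass to floating-point accuracy and has the checkable stability bound
``D * dt / h**2 <= 1/4``.  Cells withdraw solute mass from their nearest
lattice node (capped so nothing goes negative), deposit secreted products
over a small 3x3 plume around it (both operations conserve mass exactly),
and *sense* concentrations by bilinear interpolation (so growth rates vary
smoothly with position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import ndimage

from .kinetics import (
    Species,
    SpeciesParams,
    ToxicityParams,
    intermediate_conversion_rate,
    specific_growth_rate,
    substrate_conversion_rate,
)

if TYPE_CHECKING:  # pragma: no cover
    from .agents import CellPopulation

SOLUTES = ("S", "I", "P")

#: maximum stable FTCS coefficient D*dt/h^2 for the 2D five-point stencil
STABILITY_LIMIT = 0.25


class StabilityError(ValueError):
    """Raised when a diffusion step would violate the explicit scheme's bound."""


@dataclass
class SoluteFields:
    """Three concentration lattices sharing shape, spacing and boundary rule."""

    S: np.ndarray
    I: np.ndarray
    P: np.ndarray
    h: float = 1.0
    diffusion: dict = field(default_factory=lambda: {"S": 1.0, "I": 1.0, "P": 1.0})
    boundary_rule: str = "no_flux"

    def __post_init__(self):
        shapes = {self.S.shape, self.I.shape, self.P.shape}
        if len(shapes) != 1:
            raise ValueError("S, I, P lattices must share one shape")
        if self.boundary_rule != "no_flux":
            raise ValueError("only no_flux boundaries are supported")

    # -- construction -----------------------------------------------------

    @classmethod
    def uniform(cls, shape, S0: float, D=1.0, h: float = 1.0) -> "SoluteFields":
        """Plate seeded with a uniform substrate concentration S0 and no I or P.

        ``D`` may be a scalar (shared by all three solutes) or a mapping
        per solute name.
        """
        if np.isscalar(D):
            D = {name: float(D) for name in SOLUTES}
        else:
            D = {name: float(D[name]) for name in SOLUTES}
        return cls(
            S=np.full(shape, float(S0)),
            I=np.zeros(shape),
            P=np.zeros(shape),
            h=float(h),
            diffusion=D,
        )

    # -- basic queries -----------------------------------------------------

    @property
    def shape(self):
        return self.S.shape

    @property
    def extent(self):
        """(x_max, y_max) of valid positions; nodes live at 0..(n-1)*h."""
        ny, nx = self.S.shape
        return ((nx - 1) * self.h, (ny - 1) * self.h)

    def grid(self, solute: str) -> np.ndarray:
        return getattr(self, solute)

    def total_mass(self, solute: str) -> float:
        """Total solute mass on the lattice (concentration * voxel area)."""
        return float(self.grid(solute).sum() * self.h**2)

    # -- diffusion ---------------------------------------------------------

    def diffuse_step(self, dt: float) -> "SoluteFields":
        """Advance every lattice one explicit FTCS step (in place).

        Raises :class:`StabilityError` if ``dt`` violates the explicit bound
        ``dt <= h^2 / (4 * D_max)``.
        """
        d_max = max(self.diffusion.values())
        if d_max > 0 and d_max * dt / self.h**2 > STABILITY_LIMIT + 1e-12:
            raise StabilityError(
                f"dt={dt} violates the FTCS stability bound "
                f"dt <= h^2/(4*D_max) = {self.h**2 / (4 * d_max):.6g}"
            )
        for name in SOLUTES:
            D = self.diffusion[name]
            if D == 0:
                continue
            u = self.grid(name)
            alpha = D * dt / self.h**2
            up = np.pad(u, 1, mode="edge")  # reflecting: zero flux across edges
            lap = (
                up[:-2, 1:-1]
                + up[2:, 1:-1]
                + up[1:-1, :-2]
                + up[1:-1, 2:]
                - 4.0 * u
            )
            u += alpha * lap
        return self

    def diffuse(self, dt: float) -> "SoluteFields":
        """Diffuse over ``dt``, sub-stepping as required by stability."""
        d_max = max(self.diffusion.values())
        if d_max == 0:
            return self
        n_sub = max(1, int(np.ceil(d_max * dt / (STABILITY_LIMIT * self.h**2))))
        for _ in range(n_sub):
            self.diffuse_step(dt / n_sub)
        return self

    # -- sampling and deposition -------------------------------------------

    def _coords(self, positions):
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        xmax, ymax = self.extent
        if np.any(pos[:, 0] < 0) or np.any(pos[:, 0] > xmax) or np.any(
            pos[:, 1] < 0
        ) or np.any(pos[:, 1] > ymax):
            raise ValueError("position outside the grid extent")
        return pos

    def sample(self, positions, solute: str):
        """Bilinear interpolation of a lattice at arbitrary positions.

        ``positions`` is (n, 2) as (x, y) in physical units; exact at nodes.
        """
        pos = self._coords(positions)
        coords = np.vstack([pos[:, 1] / self.h, pos[:, 0] / self.h])  # row=y
        out = ndimage.map_coordinates(
            self.grid(solute), coords, order=1, mode="nearest"
        )
        return out if len(out) > 1 else float(out[0])

    def node_index(self, positions):
        """Nearest-node (row, col) indices used for mass deposition."""
        pos = self._coords(positions)
        ny, nx = self.shape
        col = np.clip(np.rint(pos[:, 0] / self.h).astype(int), 0, nx - 1)
        row = np.clip(np.rint(pos[:, 1] / self.h).astype(int), 0, ny - 1)
        return row, col

    # -- export --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (x_index, y_index, solute, value)."""
        ny, nx = self.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        frames = [
            pd.DataFrame(
                {
                    "x_index": xx.ravel(),
                    "y_index": yy.ravel(),
                    "solute": name,
                    "value": self.grid(name).ravel(),
                }
            )
            for name in SOLUTES
        ]
        return pd.concat(frames, ignore_index=True)


def diffuse_step(fields: SoluteFields, dt: float) -> SoluteFields:
    """Functional alias of :meth:`SoluteFields.diffuse_step`."""
    return fields.diffuse_step(dt)


def sample_field(fields: SoluteFields, position, solute: str):
    """Functional alias of :meth:`SoluteFields.sample`."""
    return fields.sample(position, solute)


@dataclass
class ReactionOutcome:
    """Per-step bookkeeping returned by :func:`apply_reactions`.

    ``growth_rate`` is the realized net specific growth rate per cell
    (uptake-capped, maintenance already subtracted); the delta fields are
    lattice-mass totals used by the carbon ledger.
    """

    growth_rate: np.ndarray
    substrate_converted: float
    intermediate_produced: float
    intermediate_converted: float
    product_produced: float
    product_consumed: float


def _capped_withdrawal(demand_mass, flat_idx, grid, h):
    """Withdraw per-cell demands from each cell's nearest lattice node.

    Every node scales its claimants down proportionally so it is never
    driven negative.  Returns the realized per-cell mass and applies the
    withdrawal in place; mass is conserved exactly, and a capped cell
    realizes less than it asked for.
    """
    n_nodes = grid.size
    node_demand = np.bincount(flat_idx, weights=demand_mass, minlength=n_nodes)
    avail = grid.ravel() * h**2
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(node_demand > 0, np.minimum(1.0, avail / node_demand), 1.0)
    realized = demand_mass * scale[flat_idx]
    removed = np.bincount(flat_idx, weights=realized, minlength=n_nodes)
    grid -= (removed / h**2).reshape(grid.shape)
    np.clip(grid, 0.0, None, out=grid)  # guard fp dust
    return realized


def _deposit(mass, rows, cols, grid, h):
    """Spread each cell's secreted mass over the 3x3 node neighbourhood.

    Secreted metabolites disperse over a few cell lengths before re-uptake,
    so a producer does not get exclusive first access to its own output; the
    plume is still far narrower than a species sector.  Off-grid parts of
    the kernel are clipped onto the boundary nodes, conserving mass exactly.
    """
    ny, nx = grid.shape
    added = np.zeros(ny * nx)
    w = mass / 9.0
    for dr in (-1, 0, 1):
        rr = np.clip(rows + dr, 0, ny - 1)
        for dc in (-1, 0, 1):
            cc = np.clip(cols + dc, 0, nx - 1)
            added += np.bincount(rr * nx + cc, weights=w, minlength=ny * nx)
    grid += (added / h**2).reshape(ny, nx)


def apply_reactions(
    fields: SoluteFields,
    cells: "CellPopulation",
    detox: SpeciesParams,
    cons: SpeciesParams,
    tox: ToxicityParams,
    dt: float,
    growth_scale=None,
) -> ReactionOutcome:
    """Couple cells to the lattices for one time step of length ``dt``.

    Per detoxifier: S -> I at its site (1:1 carbon stoichiometry) at rate
    nu_S(S) per unit biomass.  Per consumer: I -> P at rate nu_I(I), with the
    configured product stoichiometry.  Both species withdraw product to
    grow: the demand is the positive part of the net growth rate times
    biomass over the biomass yield.  Every sink is capped at the mass locally
    available (all claimants at a site are scaled down together), and the
    realized product uptake is fed back into the growth rate that is
    returned, so growth never uses carbon that was not actually withdrawn.

    All withdrawals are capped against the start-of-step lattices and the
    conversion products are deposited only afterwards: solute produced during
    a step becomes available to neighbours (and to its producer) after the
    following diffusion step, never within the step it was made.  This keeps
    the cell-field coupling consistent as dt shrinks — otherwise a producer
    could consume its own same-step output before diffusion has a chance to
    share it, a coupling that would strengthen as dt grows.

    ``growth_scale`` (optional, per cell in [0, 1]) multiplies the gross
    growth term before maintenance is subtracted; the engine uses it for
    contact inhibition of jammed interior cells.  Conversion reactions are
    not scaled: enzymes keep working in non-growing cells.
    """
    n = len(cells)
    if n == 0:
        return ReactionOutcome(np.empty(0), 0.0, 0.0, 0.0, 0.0, 0.0)

    pos = cells.positions
    rows, cols = fields.node_index(pos)
    flat_idx = rows * fields.shape[1] + cols
    S_loc = np.atleast_1d(fields.sample(pos, "S"))
    I_loc = np.atleast_1d(fields.sample(pos, "I"))
    P_loc = np.atleast_1d(fields.sample(pos, "P"))
    biomass = cells.biomass

    is_detox = cells.species == Species.DETOXIFIER
    is_cons = ~is_detox

    # substrate -> intermediate (detoxifier)
    demand_S = np.zeros(n)
    demand_S[is_detox] = (
        substrate_conversion_rate(S_loc[is_detox], detox) * biomass[is_detox] * dt
    )
    realized_S = _capped_withdrawal(demand_S, flat_idx, fields.S, fields.h)

    # intermediate -> product (consumer); withdrawal against start-of-step I
    demand_I = np.zeros(n)
    demand_I[is_cons] = (
        intermediate_conversion_rate(I_loc[is_cons], cons) * biomass[is_cons] * dt
    )
    realized_I = _capped_withdrawal(demand_I, flat_idx, fields.I, fields.h)
    produced_P = realized_I * np.where(is_cons, cons.product_per_intermediate, 0.0)

    # product uptake for growth (both species), capped then fed back into g
    g = np.where(
        is_detox,
        specific_growth_rate(P_loc, S_loc, detox, tox),
        specific_growth_rate(P_loc, S_loc, cons, tox),
    )
    if growth_scale is not None:
        d_arr = np.where(is_detox, detox.maintenance_d, cons.maintenance_d)
        g = (g + d_arr) * np.asarray(growth_scale) - d_arr
    yields = np.where(
        is_detox, detox.yield_biomass_per_product, cons.yield_biomass_per_product
    )
    demand_P = np.maximum(g, 0.0) * biomass * dt / yields
    realized_P = _capped_withdrawal(demand_P, flat_idx, fields.P, fields.h)
    g_realized = np.where(g > 0, realized_P * yields / (biomass * dt), g)

    # deposit this step's products only after every withdrawal is settled
    _deposit(realized_S, rows, cols, fields.I, fields.h)
    _deposit(produced_P, rows, cols, fields.P, fields.h)

    return ReactionOutcome(
        growth_rate=g_realized,
        substrate_converted=float(realized_S.sum()),
        intermediate_produced=float(realized_S.sum()),
        intermediate_converted=float(realized_I.sum()),
        product_produced=float(produced_P.sum()),
        product_consumed=float(realized_P.sum()),
    )
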