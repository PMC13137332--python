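"""The simulation loop wiring kinetics, solute fields and agents together.

One step applies, in fixed order: (1) sample local S, I, P at every cell;
(2-3) compute conversion and growth rates and apply the cell-field reactions
with uptake capping; (4) update biomass with the realized, uptake-consistent
rates; (5) divide cells at twice the birth mass; (6) remove the dead;
(7) relax disc overlaps (the mechanical range expansion); (8) diffuse the
fields; (9) advance time.  Reactions run before the biomass update so growth
can never use carbon that was not actually withdrawn from the lattice.

Randomness: one root seed spawns independent child streams for inoculum
placement and division axes, so identical (config, seed) pairs give
bit-identical trajectories.

``run_wellmixed_oracle`` integrates the spatially homogeneous ODE twin of the
model (per-capita rates times total biomass, no diffusion, no space) with an
adaptive integrator; it is the independent reference for the agent-based
dynamics in the large-diffusivity limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import agents as ag
from .fields import ReactionOutcome, SoluteFields, apply_reactions
from .kinetics import Species
from .scenario import ScenarioConfig, make_inoculum

__all__ = ["Snapshot", "Trajectory", "Simulation", "run", "run_wellmixed_oracle"]


@dataclass
class Snapshot:
    """Time-stamped colony state: cell table, geometry, optional fields."""

    time: float
    cells: pd.DataFrame
    centroid: tuple[float, float]
    inoculum_radius: float
    frontier_radius: float
    fields: SoluteFields | None = None


@dataclass
class Trajectory:
    """Ordered snapshots plus per-step aggregates for one scenario run."""

    config: ScenarioConfig
    snapshots: list[Snapshot] = field(default_factory=list)
    aggregates: pd.DataFrame | None = None
    termination_reason: str = ""
    events: list[dict] = field(default_factory=list)

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]


class Simulation:
    """Mutable simulation state for one scenario."""

    def __init__(self, config: ScenarioConfig):
        self.config = config
        root = np.random.SeedSequence(config.seed)
        placement_ss, division_ss = root.spawn(2)
        self.rng_division = np.random.default_rng(division_ss)

        self.cells = make_inoculum(
            config.inoculum.n_cells,
            config.inoculum.detox_fraction,
            config.inoculum.radius,
            placement_ss,
            center=config.grid.center,
            agent_params=config.agents,
            biomass_range=tuple(config.inoculum.biomass_range),
        )
        self.fields = SoluteFields.uniform(
            (config.grid.ny, config.grid.nx),
            S0=config.S0,
            D=config.diffusion_D,
            h=config.grid.h,
        )
        # colony reference point: biomass-weighted centroid of the inoculum
        w = self.cells.biomass
        self.centroid = (
            float(np.average(self.cells.x, weights=w)),
            float(np.average(self.cells.y, weights=w)),
        )
        self.time = 0.0
        self.step_count = 0
        self._growth_scale = np.ones(len(self.cells))
        self._agg_rows: list[dict] = []
        self.events: list[dict] = []
        self._record_aggregates(ReactionOutcome(np.empty(0), 0, 0, 0, 0, 0), 0, 0)

    # -- geometry ------------------------------------------------------------

    def frontier_radius(self) -> float:
        if len(self.cells) == 0:
            return 0.0
        return float(
            np.hypot(self.cells.x - self.centroid[0], self.cells.y - self.centroid[1]).max()
        )

    # -- bookkeeping -----------------------------------------------------------

    def _record_aggregates(self, outcome: ReactionOutcome, n_div: int, n_dead: int):
        counts = self.cells.counts()
        g = self.cells.last_growth_rate
        det = self.cells.species == Species.DETOXIFIER
        self._agg_rows.append(
            {
                "time": self.time,
                "pop_detox": counts["detoxifier"],
                "pop_cons": counts["consumer"],
                "biomass_detox": float(self.cells.biomass[det].sum()),
                "biomass_cons": float(self.cells.biomass[~det].sum()),
                "mean_g_detox": float(g[det].mean()) if det.any() else np.nan,
                "mean_g_cons": float(g[~det].mean()) if (~det).any() else np.nan,
                "frontier_radius": self.frontier_radius(),
                "divisions": n_div,
                "deaths": n_dead,
                "S_mass": self.fields.total_mass("S"),
                "I_mass": self.fields.total_mass("I"),
                "P_mass": self.fields.total_mass("P"),
                "substrate_converted": outcome.substrate_converted,
                "product_consumed": outcome.product_consumed,
            }
        )

    def snapshot(self, with_fields: bool = False) -> Snapshot:
        return Snapshot(
            time=self.time,
            cells=self.cells.to_frame(),
            centroid=self.centroid,
            inoculum_radius=self.config.inoculum.radius,
            frontier_radius=self.frontier_radius(),
            fields=self.fields if with_fields else None,
        )

    # -- the step ---------------------------------------------------------------

    def step(self) -> None:
        cfg = self.config
        dt = cfg.dt
        n_before = len(self.cells)

        if n_before > 0:
            self._clamp_positions()
            outcome = apply_reactions(
                self.fields, self.cells, cfg.detoxifier, cfg.consumer,
                cfg.toxicity, dt, growth_scale=self._growth_scale,
            )
            ag.update_biomass(self.cells, outcome.growth_rate, dt)
            ag.maybe_divide(self.cells, self.rng_division)
            self.cells, n_dead = ag.cull_dead(self.cells)
            _, residual = ag.relax_overlaps(self.cells, return_residuals=True)
            self._clamp_positions()
            self._update_crowding(residual)
            n_div = len(self.cells) + n_dead - n_before
        else:
            outcome = ReactionOutcome(np.empty(0), 0, 0, 0, 0, 0)
            n_div = n_dead = 0

        self.fields.diffuse(dt)
        self.time += dt
        self.step_count += 1
        self._record_aggregates(outcome, n_div, n_dead)

        if self.step_count % 50 == 0:
            self._sanity_check()

    def _update_crowding(self, residual):
        """Contact inhibition: jammed cells (deep residual overlap) pause growth."""
        thresh = self.config.agents.crowding_threshold
        if thresh <= 0:
            self._growth_scale = np.ones(len(self.cells))
            return
        self._growth_scale = (residual < thresh * self.cells.radius).astype(float)

    def _clamp_positions(self):
        """Keep cells inside the plate (hard wall at the grid extent)."""
        xmax, ymax = self.fields.extent
        eps = 1e-9
        np.clip(self.cells.x, 0.0, xmax - eps, out=self.cells.x)
        np.clip(self.cells.y, 0.0, ymax - eps, out=self.cells.y)

    def _sanity_check(self):
        for name in ("S", "I", "P"):
            grid = self.fields.grid(name)
            if not np.all(np.isfinite(grid)):
                raise FloatingPointError(f"non-finite values in solute {name}")
            if grid.min() < -1e-9:
                raise FloatingPointError(f"negative concentration in solute {name}")
        if len(self.cells) and not np.all(np.isfinite(self.cells.biomass)):
            raise FloatingPointError("non-finite cell biomass")

    # -- the run -----------------------------------------------------------------

    def run(self, store_fields: str = "final", progress: bool = False) -> Trajectory:
        """Step until the termination rule fires; returns the trajectory.

        ``store_fields``: "none", "final" (default) or "all" — whether
        snapshots carry the solute lattices.
        """
        cfg = self.config
        traj = Trajectory(config=cfg)
        traj.snapshots.append(self.snapshot(with_fields=(store_fields == "all")))
        next_snap = cfg.snapshot_interval
        reason = "max_time"
        while True:
            self.step()
            pop = len(self.cells)
            if pop == 0:
                reason = "extinct"
                break
            if pop >= cfg.termination.max_population:
                reason = "max_population"
                break
            if self.time >= cfg.termination.max_time - 1e-9:
                reason = "max_time"
                break
            if self.time >= next_snap - 1e-9:
                traj.snapshots.append(
                    self.snapshot(with_fields=(store_fields == "all"))
                )
                next_snap += cfg.snapshot_interval
        traj.snapshots.append(self.snapshot(with_fields=(store_fields != "none")))
        traj.aggregates = pd.DataFrame(self._agg_rows)
        traj.termination_reason = reason
        traj.events = self.events + [
            {"event": "terminated", "reason": reason, "time": self.time,
             "population": len(self.cells), "seed": cfg.seed}
        ]
        return traj


def run(config: ScenarioConfig, store_fields: str = "final") -> Trajectory:
    """Run one scenario to termination (population cap, time cap or extinction)."""
    return Simulation(config).run(store_fields=store_fields)


def run_wellmixed_oracle(
    config: ScenarioConfig,
    t_end: float | None = None,
    n_eval: int = 400,
    initial_biomass: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Integrate the spatially homogeneous ODE twin of the agent-based model.

    State: mean concentrations (S, I, P) over the plate volume and total
    biomass per species.  Per-capita rates are identical to the agent rules;
    diffusion and space drop out.  Cell death is continuous decay (no
    discrete removal).  Returns a dense time series.
    """
    cfg = config
    V = cfg.grid.nx * cfg.grid.ny * cfg.grid.h**2
    det, con, tox = cfg.detoxifier, cfg.consumer, cfg.toxicity

    def rhs(_t, y):
        S, I, P, B1, B2 = np.maximum(y, 0.0)
        from .kinetics import (
            intermediate_conversion_rate,
            specific_growth_rate,
            substrate_conversion_rate,
        )

        nu_S = substrate_conversion_rate(S, det) * B1
        nu_I = intermediate_conversion_rate(I, con) * B2
        g1 = specific_growth_rate(P, S, det, tox)
        g2 = specific_growth_rate(P, S, con, tox)
        uptake = (
            max(g1, 0.0) * B1 / det.yield_biomass_per_product
            + max(g2, 0.0) * B2 / con.yield_biomass_per_product
        )
        return [
            -nu_S / V,
            (nu_S - nu_I) / V,
            (nu_I * con.product_per_intermediate - uptake) / V,
            g1 * B1,
            g2 * B2,
        ]

    if initial_biomass is None:
        # expectation of the inoculum generator's biomass range
        n = cfg.inoculum.n_cells
        f = cfg.inoculum.detox_fraction
        lo, hi = cfg.inoculum.biomass_range
        mean_m = 0.5 * (lo + hi) * cfg.agents.birth_mass
        n_detox = round(n * f)
        initial_biomass = (n_detox * mean_m, (n - n_detox) * mean_m)
    y0 = [cfg.S0, 0.0, 0.0, initial_biomass[0], initial_biomass[1]]
    t_end = t_end if t_end is not None else cfg.termination.max_time
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="RK45", rtol=1e-8, atol=1e-10,
        t_eval=np.linspace(0.0, t_end, n_eval),
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"well-mixed oracle integration failed: {sol.message}")
    return pd.DataFrame(
        {
            "time": sol.t,
            "S": sol.y[0],
            "I": sol.y[1],
            "P": sol.y[2],
            "biomass_detox": sol.y[3],
            "biomass_cons": sol.y[4],
        }
    )
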