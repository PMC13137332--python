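"""Simulation loop: stepping, termination, determinism, the ODE oracle."""

import numpy as np
import pytest

from crossrange.agents import AgentParams
from crossrange.engine import Simulation, run, run_wellmixed_oracle
from crossrange.kinetics import Species
from crossrange.scenario import (
    GridSpec,
    InoculumSpec,
    ScenarioConfig,
    TerminationRule,
    default_species_params,
)


def small_config(**kw):
    base = dict(
        S0=15.0,
        theta=0.0,
        seed=1,
        grid=GridSpec(64, 64),
        inoculum=InoculumSpec(n_cells=20, detox_fraction=0.5, radius=4.0),
        termination=TerminationRule(max_population=300, max_time=200.0),
        snapshot_interval=2.0,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestStep:
    def test_lone_detoxifier_converts_but_starves(self):
        """With no consumers, S falls, I rises, P stays 0 and g = -d."""
        cfg = small_config(
            inoculum=InoculumSpec(n_cells=2, detox_fraction=1.0, radius=2.0),
            termination=TerminationRule(max_population=300, max_time=5.0),
        )
        sim = Simulation(cfg)
        S_before = sim.fields.total_mass("S")
        for _ in range(20):
            sim.step()
        assert sim.fields.total_mass("S") < S_before
        assert sim.fields.total_mass("I") > 0.0
        assert sim.fields.total_mass("P") == 0.0
        d = cfg.detoxifier.maintenance_d
        np.testing.assert_allclose(sim.cells.last_growth_rate, -d)

    def test_consortium_grows_and_both_species_persist(self):
        traj = run(small_config())
        assert traj.termination_reason == "max_population"
        final = traj.final.cells
        assert (final["species"] == "detoxifier").any()
        assert (final["species"] == "consumer").any()
        pops = traj.aggregates["pop_detox"] + traj.aggregates["pop_cons"]
        assert pops.iloc[-1] >= 300

    def test_population_rises_monotonically_in_benign_conditions(self):
        traj = run(small_config())
        pop = traj.aggregates["pop_detox"] + traj.aggregates["pop_cons"]
        # no deaths expected with theta=0 and ample substrate
        assert traj.aggregates["deaths"].sum() == 0
        assert (np.diff(pop) >= 0).all()


class TestRun:
    def test_termination_contract(self):
        traj = run(small_config())
        n_final = len(traj.final.cells)
        max_div = traj.aggregates["divisions"].iloc[-1]
        assert 300 <= n_final <= 300 + max_div

    def test_snapshot_times_strictly_increasing(self):
        traj = run(small_config())
        times = [s.time for s in traj.snapshots]
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_lethal_toxicity_terminates_extinct(self):
        detox = default_species_params(Species.DETOXIFIER, maintenance_d=0.2)
        cons = default_species_params(Species.CONSUMER, maintenance_d=0.2)
        cfg = small_config(
            theta=10.0, detoxifier=detox, consumer=cons,
            termination=TerminationRule(max_population=300, max_time=150.0),
        )
        traj = run(cfg)
        assert traj.termination_reason == "extinct"
        assert len(traj.final.cells) == 0

    def test_identical_seed_bitwise_identical_aggregates(self):
        a = run(small_config()).aggregates.to_csv()
        b = run(small_config()).aggregates.to_csv()
        assert a == b

    def test_different_seeds_differ(self):
        a = run(small_config(seed=1)).aggregates.to_csv()
        b = run(small_config(seed=2)).aggregates.to_csv()
        assert a != b

    def test_mass_conservation_with_reactions_disabled(self):
        """A cell-free plate only diffuses: every solute mass is constant."""
        cfg = small_config(
            inoculum=InoculumSpec(n_cells=2, detox_fraction=1.0, radius=2.0),
            termination=TerminationRule(max_population=10, max_time=3.0),
            detoxifier=default_species_params(
                Species.DETOXIFIER, catalytic_capacity=0.0, maintenance_d=0.0
            ),
        )
        sim = Simulation(cfg)
        before = sim.fields.total_mass("S")
        for _ in range(30):
            sim.step()
        assert sim.fields.total_mass("S") == pytest.approx(before, rel=1e-10)


class TestWellMixedOracle:
    def test_no_consumers_product_stays_zero(self):
        cfg = small_config(
            inoculum=InoculumSpec(n_cells=10, detox_fraction=1.0, radius=3.0)
        )
        series = run_wellmixed_oracle(cfg, t_end=20.0)
        assert series["P"].abs().max() == 0.0
        # biomass decays at the maintenance rate
        d = cfg.detoxifier.maintenance_d
        expected = series["biomass_detox"].iloc[0] * np.exp(
            -d * series["time"].iloc[-1]
        )
        assert series["biomass_detox"].iloc[-1] == pytest.approx(expected, rel=1e-4)

    def test_no_substrate_both_decay(self):
        cfg = small_config(S0=0.0)
        series = run_wellmixed_oracle(cfg, t_end=30.0)
        assert series["S"].abs().max() == 0.0
        assert series["biomass_detox"].iloc[-1] < series["biomass_detox"].iloc[0]
        assert series["biomass_cons"].iloc[-1] < series["biomass_cons"].iloc[0]

    def test_ibm_matches_oracle_in_wellmixed_limit(self):
        """Fast diffusion on a small plate: agent totals track the ODE twin.

        Contact inhibition is disabled — the ODE has no mechanics — so the
        comparison isolates the kinetics coupling.
        """
        cfg = ScenarioConfig(
            S0=10.0,
            theta=0.0,
            seed=3,
            diffusion_D=400.0,
            grid=GridSpec(32, 32),
            inoculum=InoculumSpec(n_cells=24, detox_fraction=0.5, radius=5.0),
            termination=TerminationRule(max_population=500, max_time=100.0),
            agents=AgentParams(base_radius=0.35, crowding_threshold=0.0),
            snapshot_interval=5.0,
        )
        sim = Simulation(cfg)
        det = sim.cells.species == Species.DETOXIFIER
        b0 = (
            float(sim.cells.biomass[det].sum()),
            float(sim.cells.biomass[~det].sum()),
        )
        traj = sim.run()
        agg = traj.aggregates
        t_end = agg["time"].iloc[-1]
        oracle = run_wellmixed_oracle(cfg, t_end=t_end, n_eval=2000,
                                      initial_biomass=b0)
        for col in ("biomass_detox", "biomass_cons"):
            ibm = np.interp(oracle["time"], agg["time"], agg[col])
            # compare once biomass is past the start-up transient
            sel = oracle[col] > oracle[col].iloc[0]
            rel = np.abs(ibm[sel] - oracle[col][sel]) / oracle[col][sel]
            assert np.quantile(rel, 0.95) < 0.05
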