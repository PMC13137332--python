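import numpy as np
import pandas as pd
import pytest

from crossrange.agents import AgentParams, CellPopulation
from crossrange.engine import Snapshot
from crossrange.kinetics import Species


def make_population(species, x, y, biomass=None, params=None):
    """Small hand-built population for unit tests."""
    species = np.asarray(species)
    n = len(species)
    params = params or AgentParams()
    biomass = np.ones(n) if biomass is None else np.asarray(biomass, float)
    return CellPopulation(
        species=species,
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        biomass=biomass,
        birth_mass=np.full(n, params.birth_mass),
        params=params,
    )


def make_snapshot(species, x, y, growth=None, time=0.0, centroid=(0.0, 0.0),
                  inoculum_radius=1.0):
    """Hand-built snapshot (cell table + geometry) for metric tests."""
    n = len(species)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "species": species,
            "x": x,
            "y": y,
            "biomass": np.ones(n),
            "growth_rate": np.zeros(n) if growth is None else np.asarray(growth),
            "alive": np.ones(n, dtype=bool),
        }
    )
    r = np.hypot(x - centroid[0], y - centroid[1])
    return Snapshot(
        time=time,
        cells=cells,
        centroid=centroid,
        inoculum_radius=inoculum_radius,
        frontier_radius=float(r.max()) if n else 0.0,
    )


@pytest.fixture
def detox_params():
    from crossrange.scenario import default_species_params

    return default_species_params(Species.DETOXIFIER)


@pytest.fixture
def consumer_params():
    from crossrange.scenario import default_species_params

    return default_species_params(Species.CONSUMER)
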