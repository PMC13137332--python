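"""Scenario construction: inocula, full simulation configs, parameter sweeps.

A scenario is a plate seeded with a uniform concentration of the toxic
substrate and a small, well-mixed circular inoculum of detoxifier and
consumer cells at a set ratio.  This module synthesizes those inocula
(reproducibly from a seed), bundles every tunable of the model into a
:class:`ScenarioConfig` that round-trips through YAML, and expands parameter
sweeps (toxicity x substrate x diffusivity x inoculum ratio x seeds) into
manifests of tagged configs.

Default kinetic constants
-------------------------
The per-strain constants below are model defaults chosen to place the
consortium in the regime where the product is growth-limiting at low
substrate supply but saturating at high supply, while conversion is fast
enough that cells measurably deplete the substrate around themselves.  They
are not measured strain parameters; every value can be overridden in the
config.  See docs/methods.md for the reasoning.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .agents import AgentParams, CellPopulation, relax_overlaps
from .kinetics import Species, SpeciesParams, ToxicityParams

__all__ = [
    "GridSpec",
    "InoculumSpec",
    "TerminationRule",
    "ScenarioConfig",
    "default_species_params",
    "make_inoculum",
    "make_sweep",
    "sweep_manifest",
]

#: default kinetic constants (see module docstring and docs/methods.md);
#: the conversion stage differs per strain below
DEFAULT_KINETICS = dict(
    max_growth_kg=0.3,        # 1/h
    growth_half_sat_Kg=0.1,   # C-mM
    maintenance_d=0.005,      # 1/h
    yield_biomass_per_product=1.0,
    product_per_intermediate=1.0,
)

#: detoxifier conversion (substrate -> intermediate): fast but far from
#: saturation over the experimental range, so supply scales with S0
DEFAULT_DETOXIFIER = dict(catalytic_capacity=10.5, half_saturation_K=90.0)

#: consumer conversion (intermediate -> product): capacity-limited, so the
#: product supply saturates at high substrate flux and surplus reaches the
#: detoxifier
DEFAULT_CONSUMER = dict(catalytic_capacity=0.9, half_saturation_K=2.0)


def default_species_params(species: Species, **overrides) -> SpeciesParams:
    """Default constants for one strain; keyword overrides replace defaults."""
    kw = dict(DEFAULT_KINETICS)
    kw.update(
        DEFAULT_DETOXIFIER if Species(species) is Species.DETOXIFIER
        else DEFAULT_CONSUMER
    )
    kw.update(overrides)
    return SpeciesParams(species_id=species, **kw)


@dataclass(frozen=True)
class GridSpec:
    nx: int = 144
    ny: int = 144
    h: float = 1.0

    @property
    def center(self) -> tuple[float, float]:
        return ((self.nx - 1) * self.h / 2.0, (self.ny - 1) * self.h / 2.0)


@dataclass(frozen=True)
class InoculumSpec:
    n_cells: int = 100
    detox_fraction: float = 0.5
    radius: float = 7.0
    #: initial biomass range as multiples of the birth mass
    biomass_range: tuple = (1.0, 2.0)

    def __post_init__(self):
        object.__setattr__(self, "biomass_range", tuple(self.biomass_range))


@dataclass(frozen=True)
class TerminationRule:
    max_population: int = 8100
    max_time: float = 400.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete, serializable specification of one simulation run."""

    S0: float = 15.0
    theta: float = 0.0
    hill_exponent: int = 3
    diffusion_D: float = 1.0
    detoxifier: SpeciesParams = field(
        default_factory=lambda: default_species_params(Species.DETOXIFIER)
    )
    consumer: SpeciesParams = field(
        default_factory=lambda: default_species_params(Species.CONSUMER)
    )
    grid: GridSpec = field(default_factory=GridSpec)
    inoculum: InoculumSpec = field(default_factory=InoculumSpec)
    termination: TerminationRule = field(default_factory=TerminationRule)
    agents: AgentParams = field(default_factory=AgentParams)
    dt: float = 0.1
    snapshot_interval: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.inoculum.detox_fraction <= 1.0:
            raise ValueError("detox_fraction must be in [0, 1]")
        half_extent = min(self.grid.nx, self.grid.ny) * self.grid.h / 2.0
        if self.inoculum.radius >= half_extent:
            raise ValueError("inoculum radius must be smaller than the grid half-extent")
        if self.termination.max_population < self.inoculum.n_cells:
            raise ValueError("max_population must be >= the inoculum size")
        if self.S0 < 0 or self.theta < 0 or self.diffusion_D < 0:
            raise ValueError("S0, theta and diffusion_D must be >= 0")

    @property
    def toxicity(self) -> ToxicityParams:
        return ToxicityParams(theta=self.theta, hill_exponent=self.hill_exponent)

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detoxifier"]["species_id"] = int(d["detoxifier"]["species_id"])
        d["consumer"]["species_id"] = int(d["consumer"]["species_id"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d.pop("scenario_id", None)
        d["detoxifier"] = SpeciesParams(**d["detoxifier"])
        d["consumer"] = SpeciesParams(**d["consumer"])
        d["grid"] = GridSpec(**d["grid"])
        d["inoculum"] = InoculumSpec(**d["inoculum"])
        d["termination"] = TerminationRule(**d["termination"])
        d["agents"] = AgentParams(**d["agents"])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ScenarioConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        return cls.from_dict(d)

    @property
    def scenario_id(self) -> str:
        """Deterministic tag derived from the full config content."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def with_overrides(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


def make_inoculum(
    n_cells: int,
    detox_fraction: float,
    radius: float,
    seed,
    center=(0.0, 0.0),
    agent_params: AgentParams | None = None,
    biomass_range: tuple = (1.0, 2.0),
) -> CellPopulation:
    """Well-mixed circular inoculum of the two strains.

    Cells are placed uniformly at random in a disc (rejection sampling), the
    detoxifier count is round(n * fraction), initial biomasses are uniform in
    [1, 2) x birth mass to desynchronize the first divisions, and one overlap
    relaxation is applied before return.  Fully reproducible from the seed.
    """
    if n_cells < 2:
        raise ValueError("an inoculum needs at least 2 cells")
    if not 0.0 <= detox_fraction <= 1.0:
        raise ValueError("detox_fraction must be in [0, 1]")
    params = agent_params or AgentParams()
    rng = np.random.default_rng(seed)

    pts = np.empty((0, 2))
    while len(pts) < n_cells:
        cand = rng.uniform(-radius, radius, size=(2 * n_cells, 2))
        cand = cand[np.hypot(cand[:, 0], cand[:, 1]) <= radius]
        pts = np.vstack([pts, cand])
    pts = pts[:n_cells] + np.asarray(center, dtype=float)

    n_detox = int(round(n_cells * detox_fraction))
    species = np.full(n_cells, Species.CONSUMER, dtype=np.int8)
    species[rng.permutation(n_cells)[:n_detox]] = Species.DETOXIFIER
    lo, hi = biomass_range
    if not 0 < lo <= hi:
        raise ValueError("biomass_range must be positive and ordered")
    biomass = rng.uniform(lo, hi, size=n_cells) * params.birth_mass

    pop = CellPopulation(
        species=species,
        x=pts[:, 0],
        y=pts[:, 1],
        biomass=biomass,
        birth_mass=np.full(n_cells, params.birth_mass),
        params=params,
    )
    relax_overlaps(pop)
    return pop


def make_sweep(
    theta_list,
    S0_list,
    D_list,
    fraction_list,
    seeds,
    base: ScenarioConfig | None = None,
) -> list[ScenarioConfig]:
    """Cartesian product of sweep axes, one tagged config per combination."""
    for name, lst in [
        ("theta_list", theta_list),
        ("S0_list", S0_list),
        ("D_list", D_list),
        ("fraction_list", fraction_list),
        ("seeds", seeds),
    ]:
        if len(list(lst)) == 0:
            raise ValueError(f"{name} must be non-empty")
    base = base or ScenarioConfig()
    configs = []
    for theta, S0, D, frac, seed in itertools.product(
        theta_list, S0_list, D_list, fraction_list, seeds
    ):
        cfg = base.with_overrides(
            theta=float(theta),
            S0=float(S0),
            diffusion_D=float(D),
            inoculum=replace(base.inoculum, detox_fraction=float(frac)),
            seed=int(seed),
        )
        configs.append(cfg)
    return configs


def sweep_manifest(configs) -> pd.DataFrame:
    """Flat manifest table for a sweep, exportable as CSV."""
    rows = [
        {
            "scenario_id": c.scenario_id,
            "theta": c.theta,
            "S0": c.S0,
            "diffusion_D": c.diffusion_D,
            "detox_fraction": c.inoculum.detox_fraction,
            "seed": c.seed,
        }
        for c in configs
    ]
    return pd.DataFrame(rows)
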