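"""Daily simulation loop for a set of plants sharing one soil grid.

The five competition scenarios place a target plant at the centre of the
world with 0-4 clonal or heterospecific neighbours at fixed compass
positions.  Each day the soil water is recharged, evaporated and diffused;
all plants' segment demands are pooled into a single rationing pass (so
inter-plant competition is simultaneous and symmetric); and each plant
converts its delivered water into shoot growth and root construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import ModelConstants
from .genotype import Genotype
from .plant import Plant, shoot_fraction, water_to_growth
from .soil import SoilGrid, SoilParams, diffuse, evaporate, extract_pooled, recharge

__all__ = ["Scenario", "SimulationResult", "place_plants", "run_simulation"]

#: Default within-day order of the soil phases, before uptake and growth.
DEFAULT_PROCESS_ORDER = ("recharge", "evaporate", "diffuse")


@dataclass(frozen=True)
class Scenario:
    """Competition scenario: a target with ``n_neighbours`` neighbours."""

    n_neighbours: int = 0
    neighbour_distance: float = 50.0  # mm
    duration: int = 150  # days

    def __post_init__(self) -> None:
        if self.n_neighbours not in (0, 1, 2, 3, 4):
            raise ValueError("n_neighbours must be in 0..4")
        if self.neighbour_distance <= 0:
            raise ValueError("neighbour_distance must be positive")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass
class SimulationResult:
    """Trajectories and final state of one multi-plant run."""

    shoot: np.ndarray  # (n_plants, duration + 1) g
    root: np.ndarray  # (n_plants, duration + 1) g
    plants: list[Plant]
    grid: SoilGrid
    seed: int
    water_ledger: dict = field(default_factory=dict)

    @property
    def target_final_shoot(self) -> float:
        return float(self.shoot[0, -1])


def place_plants(scenario: Scenario, world: SoilParams) -> list[np.ndarray]:
    """Base positions: target at the horizontal centre, neighbours at the
    first ``n_neighbours`` of the four compass points (N, E, S, W)."""
    if world.extent_x <= 2 * scenario.neighbour_distance or world.extent_y <= 2 * scenario.neighbour_distance:
        raise ValueError("world too small for the neighbour distance")
    cx, cy = world.extent_x / 2.0, world.extent_y / 2.0
    d = scenario.neighbour_distance
    compass = [(cx, cy - d), (cx + d, cy), (cx, cy + d), (cx - d, cy)]
    positions = [np.array([cx, cy, 0.0])]
    for k in range(scenario.n_neighbours):
        x, y = compass[k]
        positions.append(np.array([x, y, 0.0]))
    return positions


def run_simulation(
    scenario: Scenario,
    genotypes: Sequence[Genotype],
    constants: ModelConstants | None = None,
    soil_params: SoilParams | None = None,
    seed: int = 0,
    plant_seeds: Sequence[int] | None = None,
    positions: Sequence[np.ndarray] | None = None,
    process_order: tuple[str, ...] = DEFAULT_PROCESS_ORDER,
) -> SimulationResult:
    """Simulate ``scenario.duration`` days for target + neighbours.

    ``genotypes[0]`` is the target; the rest are the neighbours in compass
    order.  Each plant owns an independent RNG stream seeded from
    ``(seed, plant index)`` (or from ``plant_seeds`` when given), so a
    plant's stochastic branching is reproducible independently of the
    other plants.  The water ledger records recharge inputs, evaporation
    losses and root extraction so mass balance can be audited.
    """
    constants = constants if constants is not None else ModelConstants()
    soil_params = soil_params if soil_params is not None else SoilParams()
    if len(genotypes) != scenario.n_neighbours + 1:
        raise ValueError("need one genotype per plant (target first)")
    if positions is None:
        positions = place_plants(scenario, soil_params)

    plants = []
    for i, (g, pos) in enumerate(zip(genotypes, positions)):
        if plant_seeds is not None:
            rng = np.random.default_rng(plant_seeds[i])
        else:
            rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        plants.append(Plant(i, g, pos, constants, soil_params, rng))

    grid = SoilGrid(soil_params)
    n = len(plants)
    days = scenario.duration
    shoot = np.zeros((n, days + 1))
    root = np.zeros((n, days + 1))
    root[:, 0] = [p.root_biomass for p in plants]

    ledger = {
        "initial": grid.total_water(),
        "recharged": 0.0,
        "evaporated": 0.0,
        "extracted": 0.0,
    }
    demand = constants.segment_demand

    for day in range(days):
        for phase in process_order:
            if phase == "recharge":
                before = grid.total_water()
                recharge(grid, day)
                ledger["recharged"] += grid.total_water() - before
            elif phase == "evaporate":
                before = grid.total_water()
                evaporate(grid)
                ledger["evaporated"] += before - grid.total_water()
            elif phase == "diffuse":
                diffuse(grid)
            else:
                raise ValueError(f"unknown soil phase {phase!r}")

        # pooled uptake: one rationing pass across every plant's segments
        counts = [p.n_segments for p in plants]
        vox = np.concatenate([p.seg_voxel for p in plants])
        demands = np.full(vox.size, demand)
        realized = extract_pooled(grid, vox, demands)
        ledger["extracted"] += float(realized.sum())

        offset = 0
        for i, p in enumerate(plants):
            mine = realized[offset : offset + counts[i]]
            offset += counts[i]
            delivered = float(mine @ p.seg_discount)
            allocable = water_to_growth(delivered, constants)
            frac = shoot_fraction(allocable, p.genotype)
            p.shoot_biomass += allocable * frac
            p.grow(allocable * (1.0 - frac))
            shoot[i, day + 1] = p.shoot_biomass
            root[i, day + 1] = p.root_biomass

    ledger["final"] = grid.total_water()
    return SimulationResult(
        shoot=shoot, root=root, plants=plants, grid=grid, seed=seed, water_ledger=ledger
    )
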