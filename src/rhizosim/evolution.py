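"""Evolutionary algorithm: mutation, clonal fitness evaluation, truncation
selection, and species extraction across replicate runs.

Each generation every genotype in the population of size ``N`` is duplicated
with Gaussian perturbations of all parameters, all ``2N`` genotypes (parents
included — fitness is re-evaluated every generation) are grown for one
season in the scenario, and the top ``N`` by final shoot biomass survive.
A "species" is the set of best genotypes pooled over the replicate runs of
one scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .constants import ModelConstants
from .genotype import (
    Genotype,
    PARAM_NAMES,
    SAMPLING_RANGES,
    clip_to_limits,
    genotype_matrix,
    sample_genotype,
)
from .simulate import Scenario, run_simulation
from .soil import SoilParams

__all__ = [
    "EvolutionConfig",
    "EvolutionTrace",
    "Species",
    "default_mutation_scales",
    "mutate",
    "evaluate_fitness",
    "evolve",
    "extract_species",
    "genotype_pcoa",
]


def default_mutation_scales() -> dict[str, float]:
    """Per-parameter Gaussian sd: 5% of the initial sampling-range width."""
    return {n: 0.05 * (hi - lo) for n, (lo, hi) in SAMPLING_RANGES.items()}


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of the evolutionary algorithm."""

    population_size: int = 15
    generations: int = 500
    replicates: int = 5
    mutation_scales: Mapping[str, float] = field(default_factory=default_mutation_scales)
    duration: int = 150  # days per growth simulation
    neighbour_distance: float = 50.0  # mm
    species_size: int = 30  # genotypes pooled into a species
    snapshot_every: int = 0  # 0 = no genotype snapshots in the trace

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if any(s < 0 for s in self.mutation_scales.values()):
            raise ValueError("mutation scales must be >= 0")


@dataclass
class EvolutionTrace:
    """Per-generation fitness summary of the surviving population."""

    mean_fitness: np.ndarray
    max_fitness: np.ndarray
    snapshots: list[tuple[int, list[Genotype]]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.mean_fitness)),
                "mean_fitness": self.mean_fitness,
                "max_fitness": self.max_fitness,
            }
        )


@dataclass
class Species:
    """Best genotypes pooled across the replicate runs of one scenario."""

    label: str
    genotypes: list[Genotype]
    fitnesses: np.ndarray
    provenance: dict = field(default_factory=dict)


def mutate(genotype: Genotype, scales: Mapping[str, float], rng: np.random.Generator) -> Genotype:
    """Perturb every parameter with an independent Gaussian draw, then clip
    to the hard limits (``maxorder`` is rounded to the nearest integer)."""
    values = {}
    for name in PARAM_NAMES:
        v = float(getattr(genotype, name)) + rng.normal(0.0, scales.get(name, 0.0))
        values[name] = clip_to_limits(name, v)
    values["maxorder"] = int(values["maxorder"])
    return Genotype(**values)


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def evaluate_fitness(
    genotype: Genotype,
    scenario_id: int,
    constants: ModelConstants | None = None,
    soil_params: SoilParams | None = None,
    seed: int = 0,
    duration: int = 150,
    neighbour_distance: float = 50.0,
) -> float:
    """Final shoot biomass of the target grown with ``scenario_id`` clonal
    neighbours for one season."""
    if scenario_id not in (0, 1, 2, 3, 4):
        raise ValueError("scenario_id must be in 0..4")
    scenario = Scenario(
        n_neighbours=scenario_id,
        neighbour_distance=neighbour_distance,
        duration=duration,
    )
    result = run_simulation(
        scenario,
        [genotype] * (scenario_id + 1),
        constants=constants,
        soil_params=soil_params,
        seed=seed,
    )
    return result.target_final_shoot


def evolve(
    scenario_id: int,
    config: EvolutionConfig,
    seed: int = 0,
    constants: ModelConstants | None = None,
    soil_params: SoilParams | None = None,
    fitness_fn: Callable[[Genotype, int], float] | None = None,
) -> tuple[EvolutionTrace, list[Genotype], np.ndarray]:
    """Run one replicate of the evolutionary algorithm.

    Returns the trace, the final population of ``N`` genotypes, and their
    final recorded fitnesses.  ``fitness_fn(genotype, eval_seed)`` may
    replace the growth simulation (used by tests with surrogate fitness).
    Fitness evaluations within a generation use independent derived seeds,
    so they could run concurrently with identical results.
    """
    N = config.population_size
    rng = np.random.default_rng(np.random.SeedSequence([seed, scenario_id]))
    population = [sample_genotype(rng) for _ in range(N)]
    birth = list(range(N))  # creation order; older wins fitness ties
    next_id = N

    if fitness_fn is None:

        def fitness_fn(g: Genotype, eval_seed: int) -> float:
            return evaluate_fitness(
                g,
                scenario_id,
                constants=constants,
                soil_params=soil_params,
                seed=eval_seed,
                duration=config.duration,
                neighbour_distance=config.neighbour_distance,
            )

    mean_fit = np.empty(config.generations)
    max_fit = np.empty(config.generations)
    snapshots: list[tuple[int, list[Genotype]]] = []
    fitness = np.empty(N)

    for gen in range(config.generations):
        offspring = [mutate(g, config.mutation_scales, rng) for g in population]
        off_birth = list(range(next_id, next_id + N))
        next_id += N
        pool = population + offspring
        ages = birth + off_birth
        pool_fitness = np.array(
            [fitness_fn(g, _derived_seed(seed, scenario_id, gen, i)) for i, g in enumerate(pool)]
        )
        # truncation selection: top N by fitness, older genotype wins ties
        order = sorted(range(2 * N), key=lambda i: (-pool_fitness[i], ages[i]))
        keep = order[:N]
        population = [pool[i] for i in keep]
        birth = [ages[i] for i in keep]
        fitness = pool_fitness[keep]
        mean_fit[gen] = fitness.mean()
        max_fit[gen] = fitness.max()
        if config.snapshot_every and gen % config.snapshot_every == 0:
            snapshots.append((gen, list(population)))

    return EvolutionTrace(mean_fit, max_fit, snapshots), population, fitness


def extract_species(
    populations: Sequence[Sequence[Genotype]],
    fitnesses: Sequence[Sequence[float]],
    label: str,
    species_size: int = 30,
    expected_population_size: int | None = None,
) -> Species:
    """Pool the replicate final populations and keep the fittest genotypes.

    Ties are broken by (replicate index, position within the replicate).
    """
    if expected_population_size is not None:
        for pop in populations:
            if len(pop) != expected_population_size:
                raise ValueError("replicate population size mismatch")
    rows = []
    for run_id, (pop, fits) in enumerate(zip(populations, fitnesses, strict=True)):
        if len(pop) != len(fits):
            raise ValueError("fitness count mismatch")
        for idx, (g, f) in enumerate(zip(pop, fits)):
            rows.append((float(f), run_id, idx, g))
    if species_size > len(rows):
        raise ValueError("species_size exceeds pooled genotype count")
    rows.sort(key=lambda r: (-r[0], r[1], r[2]))
    chosen = rows[:species_size]
    return Species(
        label=label,
        genotypes=[r[3] for r in chosen],
        fitnesses=np.array([r[0] for r in chosen]),
        provenance={"pool_size": len(rows), "runs": len(populations)},
    )


def genotype_pcoa(genotypes: Sequence[Genotype]):
    """Classical MDS (principal coordinates) of standardized genotypes.

    Parameters are z-scored (constant columns dropped), pairwise Euclidean
    distances decomposed with scikit-bio's PCoA.  Returns ``(coords,
    eigen_shares)``: the first two coordinates per genotype and the
    proportion of variation per retained axis.
    """
    if len(genotypes) < 3:
        raise ValueError("need at least 3 genotypes")
    X = genotype_matrix(genotypes)
    sd = X.std(axis=0)
    keep = sd > 0
    if keep.any():
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    else:
        Z = np.zeros((len(genotypes), 1))
    diff = Z[:, None, :] - Z[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    dm = DistanceMatrix(dist, ids=[str(i) for i in range(len(genotypes))])
    res = _skbio_pcoa(dm, number_of_dimensions=min(len(genotypes) - 1, Z.shape[1] + 1))
    eig = np.asarray(res.eigvals, dtype=float)
    shares = np.asarray(res.proportion_explained, dtype=float)
    coords = np.asarray(res.samples)[:, :2] if res.samples.shape[1] >= 2 else np.zeros((len(genotypes), 2))
    if (eig > 1e-12).sum() < 2:
        coords = np.zeros((len(genotypes), 2))
    return coords, shares
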