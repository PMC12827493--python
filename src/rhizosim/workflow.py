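"""End-to-end study pipeline: evolve species under competition scenarios,
measure their root morphology, and run the factorial competition experiment.

Defaults reproduce the full study protocol (five scenarios, N = 15,
500 generations, 5 replicates, 30-genotype species, 100 experiment
replicates).  All sizes are parameters so the same pipeline runs as a
scaled-down study on a desktop; the qualitative contrasts (deeper, sparser
roots under competition; the growth-potential vs. tolerance trade-off)
emerge already at small scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ModelConstants
from .evolution import EvolutionConfig, EvolutionTrace, Species, evolve, extract_species
from .experiments import build_design, competition_indices, run_experiments, summarize
from .morphology import morphology, records_frame
from .simulate import Scenario, run_simulation
from .soil import SoilParams

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    """Everything the study computes, keyed by scenario label ``Sp_<k>``."""

    traces: dict[str, list[EvolutionTrace]]
    species: dict[str, Species]
    morphology: pd.DataFrame  # one row per measured plant, ``species`` column
    records: pd.DataFrame  # experiment records
    summary: pd.DataFrame  # per-condition means and quartiles
    indices: pd.DataFrame  # per-species growth potential, effect, response
    config: dict = field(default_factory=dict)


def run_study(
    seed: int = 0,
    scenarios: Sequence[int] = (0, 1, 2, 3, 4),
    population_size: int = 15,
    generations: int = 500,
    replicates: int = 5,
    duration: int = 150,
    species_size: int = 30,
    morphology_plants: int = 30,
    experiment_replicates: int = 100,
    experiment_neighbour_counts: Sequence[int] = (1, 2, 3, 4),
    constants: ModelConstants | None = None,
    soil_params: SoilParams | None = None,
) -> StudyResult:
    """Run the complete pipeline at the requested scale.

    Per scenario ``k``: ``replicates`` independent evolutionary runs of
    ``generations`` generations select genotypes under ``k`` clonal
    neighbours; the replicate final populations are pooled and the fittest
    ``species_size`` genotypes become species ``Sp_k``.  Each species'
    morphology is measured on plants grown alone, and the factorial
    experiment crosses all species over the neighbour counts.
    """
    species_cap = min(species_size, replicates * population_size)
    evo = EvolutionConfig(
        population_size=population_size,
        generations=generations,
        replicates=replicates,
        duration=duration,
        species_size=species_cap,
    )

    traces: dict[str, list[EvolutionTrace]] = {}
    species: dict[str, Species] = {}
    for sc in scenarios:
        label = f"Sp_{sc}"
        traces[label] = []
        pops, fits = [], []
        for rep in range(replicates):
            trace, pop, fit = evolve(
                sc, evo, seed=_sub_seed(seed, sc, rep),
                constants=constants, soil_params=soil_params,
            )
            traces[label].append(trace)
            pops.append(pop)
            fits.append(fit)
        species[label] = extract_species(pops, fits, label, species_size=species_cap)

    # morphology of plants grown alone, one per genotype up to the cap
    morph_rows = []
    labels = []
    for label, sp in species.items():
        for i, g in enumerate(sp.genotypes[:morphology_plants]):
            res = run_simulation(
                Scenario(n_neighbours=0, duration=duration), [g],
                constants=constants, soil_params=soil_params,
                seed=_sub_seed(seed, 1000, i),
            )
            morph_rows.append(morphology(res.plants[0]))
            labels.append(label)
    morph = records_frame(morph_rows, species=labels)

    design = build_design(
        sorted(species), replicates=experiment_replicates,
        base_seed=_sub_seed(seed, 2000), neighbour_counts=experiment_neighbour_counts,
    )
    pools = {label: sp.genotypes for label, sp in species.items()}
    records = run_experiments(
        design, pools, constants=constants, soil_params=soil_params, duration=duration,
    )
    summary = summarize(records)
    indices = competition_indices(
        summary, n_neighbours=max(experiment_neighbour_counts)
    )
    return StudyResult(
        traces=traces,
        species=species,
        morphology=morph,
        records=records,
        summary=summary,
        indices=indices,
        config={
            "seed": seed,
            "scenarios": list(scenarios),
            "population_size": population_size,
            "generations": generations,
            "replicates": replicates,
            "duration": duration,
            "species_size": species_cap,
            "experiment_replicates": experiment_replicates,
        },
    )


def _sub_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))
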