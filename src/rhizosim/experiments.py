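"""Factorial competition experiments and competitive-ability indices.

The design crosses 5 target species x 5 neighbour species x 1-4
neighbours, plus the 5 alone conditions: ``(5 x 5 x 4) + 5 = 105``
conditions.  Every replicate of a condition draws the target's and each
neighbour's genotype independently from the corresponding species pool,
grows the stand for one season, and records the target's final shoot
biomass.  Condition summaries feed simple ratio-to-alone indices of
competitive effect (suppression exerted) and response (suppression
tolerated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import ModelConstants
from .genotype import Genotype
from .simulate import Scenario, run_simulation
from .soil import SoilParams

__all__ = [
    "ExperimentDesign",
    "build_design",
    "condition_sim_seed",
    "run_experiments",
    "summarize",
    "competition_indices",
]


@dataclass(frozen=True)
class Condition:
    index: int
    target: str
    neighbour: str | None  # None for the alone conditions
    n_neighbours: int


@dataclass
class ExperimentDesign:
    """Enumerated factorial conditions with deterministic per-replicate seeds."""

    species: list[str]
    conditions: list[Condition]
    replicates: int
    base_seed: int
    neighbour_counts: tuple[int, ...] = (1, 2, 3, 4)

    def __len__(self) -> int:
        return len(self.conditions)


def build_design(
    species_labels: Sequence[str],
    replicates: int = 100,
    base_seed: int = 0,
    neighbour_counts: Sequence[int] = (1, 2, 3, 4),
) -> ExperimentDesign:
    """Enumerate the factorial design: every (target, neighbour species,
    neighbour count) cell plus one alone condition per target."""
    labels = list(species_labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species labels")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    conditions = []
    idx = 0
    for target in labels:
        conditions.append(Condition(idx, target, None, 0))
        idx += 1
    for target in labels:
        for neighbour in labels:
            for k in neighbour_counts:
                conditions.append(Condition(idx, target, neighbour, int(k)))
                idx += 1
    return ExperimentDesign(
        species=labels,
        conditions=conditions,
        replicates=replicates,
        base_seed=base_seed,
        neighbour_counts=tuple(int(k) for k in neighbour_counts),
    )


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def condition_sim_seed(design: ExperimentDesign, condition_index: int, replicate: int) -> int:
    """Growth-simulation seed for one (condition, replicate) cell."""
    return _derived_seed(design.base_seed, condition_index, replicate, 99)


def _draw_genotype(pool: Sequence[Genotype], design: ExperimentDesign, cond: int, rep: int, plant: int) -> Genotype:
    """Uniform draw from a species pool on a per-plant stream, so neighbour
    draws never consume the target's randomness."""
    rng = np.random.default_rng(np.random.SeedSequence([design.base_seed, cond, rep, plant]))
    return pool[int(rng.integers(len(pool)))]


def run_experiments(
    design: ExperimentDesign,
    pools: Mapping[str, Sequence[Genotype]],
    constants: ModelConstants | None = None,
    soil_params: SoilParams | None = None,
    duration: int = 150,
    neighbour_distance: float = 50.0,
) -> pd.DataFrame:
    """Run every (condition, replicate) cell; one row per record.

    Columns: target, neighbour, n_neighbours, replicate, seed,
    target_biomass (final shoot biomass of the target, g).
    """
    for label in design.species:
        if label not in pools or len(pools[label]) == 0:
            raise ValueError(f"empty genotype pool for species {label!r}")
    rows = []
    for cond in design.conditions:
        for rep in range(design.replicates):
            target_g = _draw_genotype(pools[cond.target], design, cond.index, rep, 0)
            genotypes = [target_g]
            for j in range(cond.n_neighbours):
                genotypes.append(
                    _draw_genotype(pools[cond.neighbour], design, cond.index, rep, j + 1)
                )
            seed = condition_sim_seed(design, cond.index, rep)
            scenario = Scenario(
                n_neighbours=cond.n_neighbours,
                neighbour_distance=neighbour_distance,
                duration=duration,
            )
            result = run_simulation(
                scenario, genotypes, constants=constants, soil_params=soil_params, seed=seed
            )
            rows.append(
                {
                    "target": cond.target,
                    "neighbour": cond.neighbour if cond.neighbour is not None else "none",
                    "n_neighbours": cond.n_neighbours,
                    "replicate": rep,
                    "seed": seed,
                    "target_biomass": result.target_final_shoot,
                }
            )
    return pd.DataFrame(rows)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Condition-level summary: replicate count, mean, and 25th/75th
    quantiles (linear interpolation) of the target's final shoot biomass."""
    if records.empty:
        raise ValueError("no records")
    grouped = records.groupby(["target", "neighbour", "n_neighbours"], as_index=False)
    out = grouped.agg(
        n=("target_biomass", "size"),
        mean_biomass=("target_biomass", "mean"),
        q25=("target_biomass", lambda s: s.quantile(0.25)),
        q75=("target_biomass", lambda s: s.quantile(0.75)),
    )
    return out


def competition_indices(summary: pd.DataFrame, n_neighbours: int = 4) -> pd.DataFrame:
    """Per-species competitive effect and response from the summary table.

    response(T) = mean over neighbour species N of
    ``biomass(T with n x N) / biomass(T alone)`` — the fraction of solo
    growth retained under competition (higher = more tolerant).
    effect(N) = mean over targets T of ``1 - biomass(T with n x N) /
    biomass(T alone)`` — the average relative suppression a species exerts
    (higher = more suppressive).  Also reports each species' growth
    potential (mean shoot biomass when alone).
    """
    alone = summary[(summary["neighbour"] == "none") & (summary["n_neighbours"] == 0)]
    alone_map = dict(zip(alone["target"], alone["mean_biomass"]))
    crowd = summary[(summary["neighbour"] != "none") & (summary["n_neighbours"] == n_neighbours)]
    species = sorted(set(summary["target"]))
    for sp in species:
        if sp not in alone_map:
            raise ValueError(f"missing alone baseline for species {sp!r}")
    ratio = {}
    for _, row in crowd.iterrows():
        ratio[(row["target"], row["neighbour"])] = row["mean_biomass"] / alone_map[row["target"]]
    rows = []
    for sp in species:
        resp = [ratio[(sp, n)] for n in species if (sp, n) in ratio]
        eff = [1.0 - ratio[(t, sp)] for t in species if (t, sp) in ratio]
        rows.append(
            {
                "species": sp,
                "growth_potential": alone_map[sp],
                "response": float(np.mean(resp)) if resp else np.nan,
                "effect": float(np.mean(eff)) if eff else np.nan,
            }
        )
    return pd.DataFrame(rows)
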