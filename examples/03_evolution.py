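"""Evolve root architectures under two competition intensities.

A small evolutionary run (N = 8 genotypes, 20 generations) under the solo
scenario S_0 and the crowded scenario S_4.  Each generation duplicates and
mutates every genotype, grows all 2N of them for a season (neighbours are
clones of the target), and keeps the fittest half by final shoot biomass.
Mean fitness climbs steeply as allocation and architecture parameters are
tuned; the crowded scenario plateaus lower because neighbours drain the
shared water.
"""

import rhizosim as rz

config = rz.EvolutionConfig(population_size=8, generations=20, replicates=1)

for scenario_id in (0, 4):
    trace, population, fitness = rz.evolve(scenario_id, config, seed=11)
    print(f"scenario S_{scenario_id}:")
    for gen in (0, 4, 9, 14, 19):
        print(f"  gen {gen + 1:2d}: mean {trace.mean_fitness[gen]:7.3f} g   "
              f"max {trace.max_fitness[gen]:7.3f} g")
    best = population[0]
    print(f"  best genotype: gravitrop={best.gravitrop:.3f}, "
          f"branchang={best.branchang:.3f}, basezonep={best.basezonep:.3f}")
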