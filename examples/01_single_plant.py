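"""Grow one plant alone for a season and watch its biomass accumulate.

A vigorous root-first genotype is grown for 150 daily steps in the default
20 x 20 x 140 cm voxel world and its trajectory is printed.  Shoot biomass
is the fitness currency of the whole study; root biomass is the cost the
plant paid to acquire the water behind it.  (Try replacing the genotype
with ``rz.sample_genotype(numpy.random.default_rng())`` — most random
parameter sets grow far less vigorously, which is what the evolutionary
algorithm is for.)
"""

import rhizosim as rz

genotype = rz.Genotype(rotang=0.9, branchang=1.45, gravitrop=0.05, basezonelength=30,
                       basezonep=0.1, maxorder=8, orderweightings=1.3,
                       kshoot1=-1.8, kshoot2=0.006)
print("genotype:", genotype)

result = rz.run_simulation(rz.Scenario(n_neighbours=0, duration=150), [genotype], seed=42)
plant = result.plants[0]

for day in (0, 30, 60, 90, 120, 150):
    print(f"day {day:3d}: shoot {result.shoot[0, day]:8.4f} g   root {result.root[0, day]:8.4f} g")
print(f"final structure: {plant.n_segments} segments on {plant.n_branches} branches, "
      f"max depth {plant.seg_end[:, 2].max():.0f} mm")

led = result.water_ledger
balance = led["initial"] + led["recharged"] - led["evaporated"] - led["extracted"] - led["final"]
print(f"water ledger closes to {balance:.2e} mm^3 (recharge in, evaporation and uptake out)")
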