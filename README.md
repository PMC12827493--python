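# rhizosim

A functional–structural root-architecture simulator for studying how
below-ground competition for water shapes the evolution of root systems —
and how the evolved architectures trade growth potential against
competitive effect (suppressing neighbours) and competitive response
(tolerating them).

`rhizosim` is aimed at plant ecologists and crop modellers who want a
fast, fully reproducible sandbox for questions like *does selection under
crowding favour deep, sparse roots?* or *is there a globally optimal
rooting strategy?* Everything the package consumes it also generates:
there are no external data dependencies.

## The model in brief

**Soil.** A 20 × 20 × 140 cm world of 10 × 10 × 70 cubic voxels (side
20 mm). Each voxel holds water up to `side³ · whc = 800 mm³`. Daily
processes: full recharge, evaporation of a fraction (0.5) of the top
layer, and synchronous diffusion moving `diffuseperday/6` of each voxel's
water to each face neighbour (horizontal edges wrap around; no flux
through the top or bottom face).

**Plants.** A plant is a shoot biomass scalar plus an explicit root
system: branches made of 2-mm segments. Each segment demands
`waterUptakePerRootLength · SegmentLength = 20 mm³` per day from its
voxel; when a voxel cannot cover the summed demand of *all* segments in
it — from any plant — each claimant receives `demand · water/total`.
That per-voxel proportional rationing is the entire competition
mechanism. Delivered water is discounted by `(1 − c)^path` per mm of
path back to the base (c = 0.002), converted to biomass at
`10⁻⁵ g mm⁻³`, and split between shoot and root by a logistic
`σ(k₁ + k₂ · allocable[mg])`. The root share funds tip elongation
(≤ 5 mm/day per tip, shared across tips by `orderweightings^order`
priority weights) and lateral branching controlled by nine evolvable
architecture parameters (angles, gravitropism, base-zone probability,
maximum order, allocation coefficients).

**Evolution.** A population of N = 15 genotypes evolves for 500
generations: each generation every genotype is duplicated with Gaussian
parameter perturbations, all 30 are grown for a 150-day season with
clonal neighbours under one of five scenarios S₀–S₄ (0–4 neighbours
50 mm away), and the 15 with the highest final shoot biomass survive.
Pooling replicate runs and keeping the fittest genotypes yields a
"species" Sp₀–Sp₄ per scenario.

**Analysis.** Seven whole-root-system morphology metrics (depth,
horizontal reach, biomass, length per biomass, branches per length,
density per occupied voxel, box-counting fractal dimension) with a PCA
summary; a `(5 × 5 × 4) + 5 = 105`-condition factorial competition
experiment; and ratio-to-alone indices of competitive effect and
response.

## A worked example

```python
import rhizosim as rz

genotype = rz.Genotype(rotang=0.9, branchang=1.45, gravitrop=0.05,
                       basezonelength=30, basezonep=0.1, maxorder=8,
                       orderweightings=1.3, kshoot1=-1.8, kshoot2=0.006)

solo  = rz.run_simulation(rz.Scenario(n_neighbours=0, duration=150), [genotype], seed=7)
crowd = rz.run_simulation(rz.Scenario(n_neighbours=4, duration=150), [genotype] * 5, seed=7)
print(solo.target_final_shoot, crowd.target_final_shoot)
```

prints

```
11.255112018582174 1.5705459393745163
```

alone this wide-foraging genotype builds ~6 400 root segments and 11.3 g
of shoot; surrounded by four clones it keeps only 14 % of that — the
clones' root systems overlap and the per-voxel rationing splits the same
water five ways. The `examples/` directory walks through each
capability: single-plant growth, competition, evolution under S₀ vs S₄,
morphology + PCA, and the factorial experiment with effect/response
indices (run them as `python examples/01_single_plant.py` etc.).

A thin CLI wraps the same workflows:

```bash
rhizosim simulate --seed 1 --neighbours 2 --out runs/demo
rhizosim evolve --scenario 4 --seed 1 --out runs/sp4
```

## Layout

- `src/rhizosim/soil.py` — voxel grid, recharge/evaporation/diffusion, rationed extraction
- `src/rhizosim/genotype.py`, `constants.py` — evolvable parameters and model constants
- `src/rhizosim/plant.py` — array-backed root systems and daily physiology
- `src/rhizosim/simulate.py` — scenario geometry and the daily loop
- `src/rhizosim/evolution.py` — mutation, truncation selection, species, genotype PCoA
- `src/rhizosim/morphology.py` — the seven metrics and their PCA
- `src/rhizosim/experiments.py` — factorial design, summaries, effect/response indices
- `src/rhizosim/workflow.py` — the end-to-end study pipeline
- `docs/methods.md` — model assumptions, parameter tables, design choices, limitations
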