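# Methods

This note documents the model implemented by `rhizosim`, the assumptions
taken where the model family leaves the functional form open,
the numerical conventions, and what the scaled-down study settings do and
do not demonstrate.

## Soil water balance

The soil is a lattice of `nx × ny × nz` cubic voxels (defaults 10 × 10 ×
70, side 20 mm), z increasing downward from the surface. Voxel water is
bounded by `capacity = side³ · whc` (800 mm³ at defaults). Per daily
step, in this order (the order is configurable; the model family fixes
only recharge first, then uptake, then growth):

1. **Recharge** refills every voxel to capacity every
   `recharge_interval` days (default 1, i.e. daily). With daily recharge
   the vertical water profile each day is set entirely by same-day
   evaporation and uptake; the interval is exposed to allow drier
   regimes.
2. **Evaporation** multiplies the top layer by `1 − evaporation_rate`
   (default 0.5).
3. **Diffusion** stages `diffuseperday` (0.1) of each voxel's water and
   sends 1/6 of it to each face neighbour. The update is synchronous
   (Jacobi): outflows are computed from the pre-step state, which is the
   only enumeration-order-independent choice and conserves water to
   machine precision. Horizontal faces wrap around (toroidal world);
   the would-be flux through the top face of layer 0 and the bottom face
   of the last layer stays in the source voxel — the simplest convention
   that conserves mass without redistributing to the remaining faces.
4. **Uptake**: every root segment demands
   `waterUptakePerRootLength · SegmentLength = 20 mm³` from the voxel
   containing its midpoint. All demands — across all plants — are pooled
   into a single rationing pass: when a voxel's total demand exceeds its
   water, each claimant receives `demand · water/total`. This pooled,
   plant-blind rationing is the competition mechanism; no other
   interaction exists in the model.

Coordinates: voxels are half-open `[k·side, (k+1)·side)` per axis; x and
y wrap modulo the world extent; points above the surface or below the
floor are outside (segments there demand nothing).

## Plant growth

A plant is a shoot biomass scalar plus branches of 2-mm segments.
Initialisation: one order-0 branch, one segment straight down, no shoot.

Daily, per plant: delivered water = Σ per-segment uptake ×
`(1 − c)^path`, with `c = waterTransEffiiciency = 0.002` per mm of path
from the segment's proximal end to the base. Applying the transport
constant as a per-mm multiplicative discount is an **assumption** —
the constant itself does not dictate a functional form; it prices deep and distal
root length realistically, and `c = 0` recovers the plain sum. Delivered
water converts to allocable biomass at `waterToBiomass = 10⁻⁵ g mm⁻³`.

**Shoot/root allocation** is `σ(kshoot1 + kshoot2 · allocable_mg)` with
σ the logistic function — also an **assumption**; all that is fixed is
that the fraction depends on the obtained biomass through the two
coefficients. The logistic suits the sampled ranges (`kshoot1 ∈ [−5, 5]`
straddles zero; `kshoot2 ∈ [−0.1, 0.03]` is numerically meaningful when
the day's allocable biomass is expressed in milligrams). Successful
evolved genotypes typically find `kshoot1 ≪ 0` with small positive
`kshoot2`: root-first growth switching to shoot once daily income is
large.

**Root construction.** Each branch tip may elongate up to
`maxElongationRate = 5` mm/day, costing `segment_cost/SegmentLength` per
mm, where `segment_cost = π r² · SegmentLength · biomassPerVolume`
(≈ 0.00157 g at the default radius r = 0.5 mm). The constants give
biomass per root volume but no radius; the fixed-cylinder cost keeps
biomass exactly linear in length — the only property the dynamics use —
and makes total root length per biomass a constant 1 273 mm g⁻¹ (so that
morphology metric carries no between-plant signal here and the PCA drops
it). When the day's root budget cannot fund all tips, it is divided
proportionally to `orderweightings^order` (power form chosen over a
per-order lookup), capped at each tip's demand with the surplus
re-shared among unfilled tips (water-filling) — order-independent and
exactly budget-conserving. Funded length accumulates per tip; whole
segments are emitted when the carryover crosses 2 mm (the floor is
guarded by a 10⁻⁹ tolerance against round-off in the
biomass↔length conversion), so the biomass ledger closes up to less than
one segment cost per tip.

New segment direction = `normalize(heading + gravitrop · ẑ)`: an
additive downward pull per segment, the simplest operator that is
monotone in `gravitrop`. At each interior junction (the branch's own
origin never branches — avoiding two branches at one point), a lateral
is initiated with probability `basezonep` within `basezonelength` mm of
the branch origin and probability `branch_probability` (default 1)
beyond it, provided the parent's order is below `maxorder`. The
lateral's heading is the parent axis tilted by `branchang` towards a
perpendicular whose azimuth advances by `laterals_emitted · rotang`
(cumulative phyllotactic phase); the reference perpendicular is
`axis × ẑ`, or the x-axis for vertical parents.

Stochasticity: the branching draws are the model's only randomness.
Each plant owns a generator seeded from `(run seed, plant index)`, and
draws are consumed in branch-index order, so structures are bit-for-bit
reproducible and independent of the other plants in the stand.

## Scenarios, evolution, species

Scenario S_k places the target at the world's horizontal centre and k
neighbours at the first k compass points (N, E, S, W) 50 mm away —
deterministic placement removes layout variance from scenario
comparisons (random azimuths are available for robustness checks).
Seasons last 150 daily steps; shoot biomass is fitness.

The evolutionary algorithm: N genotypes (default 15) sampled uniformly
from the initial ranges; each generation all N are duplicated and every
parameter of each copy is perturbed by an independent Gaussian draw and
clipped to its hard limits (`maxorder` mutates in continuous space and
rounds to the nearest integer in [2, 9]). The mutation standard
deviations default to 5 % of each parameter's initial sampling-range
width — a scale-aware default for magnitudes the protocol leaves open. All 2N genotypes (parents are
re-evaluated every generation, accepting noisy-fitness fluctuation in
the max) are grown with clonal neighbours and the top N survive; ties go
to the older genotype. Replicate final populations are pooled and the
fittest `species_size` genotypes form the species. Population size, replicates and species size are all configuration,
with N = 15 / 5 replicates / 30-genotype species as defaults. The
out-of-base-zone branching probability is exposed as a tenth,
non-evolving configuration constant (default 1) alongside the nine
evolvable parameters.

Genotype similarity across generations is summarised by classical MDS
(PCoA) on Euclidean distances between z-scored parameter vectors
(scikit-bio's implementation); morphology across species by PCA on
z-scored metrics (scikit-learn), components sign-fixed so the dominant
loading is positive.

## Morphology metrics

Seven per-plant measures: maximum horizontal endpoint distance from the
base and maximum endpoint depth (both in unwrapped coordinates, hence
translation-invariant through the toroidal world); root biomass; total
length per biomass; branch count per total length; biomass per occupied
voxel (voxels containing ≥ 1 segment midpoint; mean-per-occupied-voxel
is the same number); and the box-counting fractal dimension. The
dimension rasterizes segments into points every 1 mm (at step midpoints,
so junctions are not double-counted), counts occupied cubes at dyadic
sides 40/20/10/5 mm anchored at the structure's minimum corner, and
takes the negative slope of the least-squares line of log N(s) vs log s.
It is computed in native 3D (the classical method is 2D on images; these
structures are natively 3D). A structure occupying one box at every
scale has no defined slope and is recorded as NaN.

## Competition experiment and indices

The factorial design crosses target species × neighbour species ×
neighbour count (1–4) plus one alone condition per target:
`(5 × 5 × 4) + 5 = 105` conditions. Replicates default to 100 (50 is a common lighter setting; any count
is configuration).
Every plant in every replicate draws its genotype uniformly from its
species pool on an independent per-plant stream, so neighbour draws
never consume the target's randomness and comparisons across neighbour
counts are stable. Summaries are per-condition mean and 25th/75th
quantiles (linear interpolation).

The effect/response indices are package-defined ratio-to-alone
formulas implementing the verbal definitions of suppression and
tolerance: `response(T) = mean_N biomass(T | 4×N) / biomass(T alone)`
(higher = more tolerant) and `effect(N) = mean_T 1 − biomass(T | 4×N) /
biomass(T alone)` (higher = more suppressive). Both lie in [0, 1] when
competition only reduces biomass; with few replicates, sampling noise in
the genotype draws can push single cells slightly above the alone
baseline.

## Problem sizes used by the tests and the acceptance script

The full protocol (5 scenarios × 5 replicates × 500 generations, and
105 conditions × 100 replicates) is hours of CPU. The package's own
scaled study — used by the test suite (seed 0) and `scripts/acceptance.py`
(caller's seed) — runs scenarios S₀ and S₄ with N = 8, 50 generations,
3 replicates, full 150-day seasons, 8-genotype species, and an
alone-plus-four-neighbours experiment with 6 replicates per condition.
At this scale mean fitness typically grows a hundred-fold and the
trade-off structure (every species best alone; the solo-evolved species
more suppressive, less tolerant, with higher growth potential) emerges
reliably. The *morphological* contrast is less robust: the fitness
landscape has at least two distinct peaks — a wide shallow-dense
forager and a deep-diving habit that exploits the daily-refilled deep
column through a few long axes — and with only 3 replicates of 50
generations, which peak a scenario's species lands on varies with the
seed. When a solo-scenario run finds the deep peak, the expected
"crowding selects deeper roots" ordering (and with it the conspecific
ranking reversal) can invert for that seed. Passing at this scale
therefore demonstrates the competition mechanism and the trade-off
direction; the depth ordering should be read as a full-scale
(many-replicate, many-generation) expectation.

## Known limitations

- No root turnover, secondary thickening, hydraulic architecture beyond
  the per-mm transport discount, nutrient fields, or above-ground
  competition; at most 5 plants per world.
- Daily full recharge makes deep water as reliable as shallow water,
  which weakens (but does not remove) the cost asymmetry between deep
  and shallow foraging; drier regimes need `recharge_interval > 1`.
- The logistic allocation and per-mm transport discount are assumed
  functional forms; conclusions that hinge on their curvature should be
  checked against alternatives.
- The fixed-radius segment cost makes specific root length a constant;
  between-architecture variation in tissue economics is out of scope.
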