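"""Segment-based root systems and per-day plant physiology.

A plant is two biomass compartments — an explicit 3D root structure and a
scalar shoot — plus a genotype.  The root system is a collection of
branches; a branch is a chain of fixed-length linear segments.  Each day a
plant demands water through its segments, converts the delivered water into
biomass, splits it between shoot and root, and spends the root share on tip
elongation and lateral branching.

Internally segments and branches live in growable numpy arrays so that the
daily loop is vectorized over branches; the per-segment/branch views are
exposed through read-only properties and a tidy-frame export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .constants import ModelConstants
from .genotype import Genotype
from .soil import OUTSIDE, SoilParams, locate_voxels_flat

__all__ = [
    "Plant",
    "init_plant",
    "segment_cost",
    "water_demands",
    "delivered_water",
    "water_to_growth",
    "shoot_fraction",
    "grow_roots",
]

_DOWN = np.array([0.0, 0.0, 1.0])  # z increases downward from the surface


def segment_cost(constants: ModelConstants) -> float:
    """Biomass cost of one root segment (g): cylinder volume x tissue density."""
    return constants.segment_cost


def shoot_fraction(allocable: float, genotype: Genotype) -> float:
    """Fraction of the day's allocable biomass routed to the shoot.

    Logistic in an affine function of the allocable biomass expressed in
    milligrams: ``expit(kshoot1 + kshoot2 * allocable_mg)``.  Strictly
    inside (0, 1) and monotone in the allocable amount with the sign of
    ``kshoot2``.
    """
    if allocable < 0:
        raise ValueError("allocable biomass must be >= 0")
    return float(expit(genotype.kshoot1 + genotype.kshoot2 * allocable * 1000.0))


def water_to_growth(delivered: float, constants: ModelConstants) -> float:
    """Convert delivered water (mm^3) into allocable biomass (g)."""
    if delivered < 0:
        raise ValueError("delivered water must be >= 0")
    return delivered * constants.water_to_biomass


class Plant:
    """One plant: genotype, shoot biomass, and an array-backed root system.

    Branch arrays (length ``n_branches``):

    - ``br_parent`` — parent branch index, -1 for the base branch
    - ``br_order`` — branching order (base = 0)
    - ``br_heading`` — current tip heading (unit vector)
    - ``br_tip`` — tip position (unwrapped world mm)
    - ``br_carry`` — funded-but-unspent elongation length (mm, < segment_length)
    - ``br_nseg`` — segments on the branch
    - ``br_base_path`` — path length (mm) from the branch origin to the plant base
    - ``br_laterals`` — laterals emitted so far (phyllotactic phase counter)

    Segment arrays (length ``n_segments``): start/end points, branch index,
    order, path length from the proximal end to the base, flat soil-voxel
    index of the midpoint, and the transport discount factor.
    """

    def __init__(
        self,
        plant_id: int,
        genotype: Genotype,
        base,
        constants: ModelConstants,
        soil_params: SoilParams,
        rng: np.random.Generator,
    ):
        self.id = plant_id
        self.genotype = genotype
        self.constants = constants
        self.soil_params = soil_params
        self.rng = rng
        self.base = np.asarray(base, dtype=float)
        if self.base.shape != (3,) or self.base[2] != 0.0:
            raise ValueError("base must be a 3-point on the soil surface (z = 0)")
        self.shoot_biomass = 0.0

        self._seg_cap = 64
        self._n_seg = 0
        self._s_start = np.empty((self._seg_cap, 3))
        self._s_end = np.empty((self._seg_cap, 3))
        self._s_branch = np.empty(self._seg_cap, dtype=np.int64)
        self._s_order = np.empty(self._seg_cap, dtype=np.int64)
        self._s_path = np.empty(self._seg_cap)
        self._s_voxel = np.empty(self._seg_cap, dtype=np.int64)
        self._s_disc = np.empty(self._seg_cap)

        self._br_cap = 16
        self._n_br = 0
        self._b_parent = np.empty(self._br_cap, dtype=np.int64)
        self._b_order = np.empty(self._br_cap, dtype=np.int64)
        self._b_origin = np.empty((self._br_cap, 3))
        self._b_heading = np.empty((self._br_cap, 3))
        self._b_tip = np.empty((self._br_cap, 3))
        self._b_carry = np.empty(self._br_cap)
        self._b_nseg = np.empty(self._br_cap, dtype=np.int64)
        self._b_base_path = np.empty(self._br_cap)
        self._b_laterals = np.empty(self._br_cap, dtype=np.int64)

        # base branch: order 0, heading straight down, one segment
        self._add_branches(
            parent=np.array([-1]),
            order=np.array([0]),
            origin=self.base[None, :],
            heading=_DOWN[None, :],
            base_path=np.array([0.0]),
        )
        self._append_segments(np.array([0]))

    # ------------------------------------------------------------------ state
    @property
    def n_segments(self) -> int:
        return self._n_seg

    @property
    def n_branches(self) -> int:
        return self._n_br

    @property
    def root_biomass(self) -> float:
        return self._n_seg * self.constants.segment_cost

    @property
    def seg_start(self) -> np.ndarray:
        return self._s_start[: self._n_seg]

    @property
    def seg_end(self) -> np.ndarray:
        return self._s_end[: self._n_seg]

    @property
    def seg_branch(self) -> np.ndarray:
        return self._s_branch[: self._n_seg]

    @property
    def seg_order(self) -> np.ndarray:
        return self._s_order[: self._n_seg]

    @property
    def seg_path(self) -> np.ndarray:
        return self._s_path[: self._n_seg]

    @property
    def seg_voxel(self) -> np.ndarray:
        return self._s_voxel[: self._n_seg]

    @property
    def seg_discount(self) -> np.ndarray:
        return self._s_disc[: self._n_seg]

    @property
    def branch_order(self) -> np.ndarray:
        return self._b_order[: self._n_br]

    @property
    def branch_parent(self) -> np.ndarray:
        return self._b_parent[: self._n_br]

    @property
    def branch_carryover(self) -> np.ndarray:
        return self._b_carry[: self._n_br]

    def segments_frame(self) -> pd.DataFrame:
        """Flat tidy table of all segments (one row per segment)."""
        return pd.DataFrame(
            {
                "plant_id": self.id,
                "branch_id": self.seg_branch,
                "order": self.seg_order,
                "x0": self.seg_start[:, 0],
                "y0": self.seg_start[:, 1],
                "z0": self.seg_start[:, 2],
                "x1": self.seg_end[:, 0],
                "y1": self.seg_end[:, 1],
                "z1": self.seg_end[:, 2],
                "path_mm": self.seg_path,
            }
        )

    # -------------------------------------------------------------- internals
    def _grow_seg_arrays(self, extra: int) -> None:
        need = self._n_seg + extra
        if need <= self._seg_cap:
            return
        cap = max(need, self._seg_cap * 2)
        for name in ("_s_start", "_s_end"):
            arr = getattr(self, name)
            new = np.empty((cap, 3))
            new[: self._n_seg] = arr[: self._n_seg]
            setattr(self, name, new)
        for name in ("_s_branch", "_s_order", "_s_voxel"):
            arr = getattr(self, name)
            new = np.empty(cap, dtype=np.int64)
            new[: self._n_seg] = arr[: self._n_seg]
            setattr(self, name, new)
        for name in ("_s_path", "_s_disc"):
            arr = getattr(self, name)
            new = np.empty(cap)
            new[: self._n_seg] = arr[: self._n_seg]
            setattr(self, name, new)
        self._seg_cap = cap

    def _grow_br_arrays(self, extra: int) -> None:
        need = self._n_br + extra
        if need <= self._br_cap:
            return
        cap = max(need, self._br_cap * 2)
        for name in ("_b_origin", "_b_heading", "_b_tip"):
            arr = getattr(self, name)
            new = np.empty((cap, 3))
            new[: self._n_br] = arr[: self._n_br]
            setattr(self, name, new)
        for name in ("_b_parent", "_b_order", "_b_nseg", "_b_laterals"):
            arr = getattr(self, name)
            new = np.empty(cap, dtype=np.int64)
            new[: self._n_br] = arr[: self._n_br]
            setattr(self, name, new)
        for name in ("_b_carry", "_b_base_path"):
            arr = getattr(self, name)
            new = np.empty(cap)
            new[: self._n_br] = arr[: self._n_br]
            setattr(self, name, new)
        self._br_cap = cap

    def _add_branches(self, parent, order, origin, heading, base_path) -> None:
        k = len(parent)
        self._grow_br_arrays(k)
        i, j = self._n_br, self._n_br + k
        self._b_parent[i:j] = parent
        self._b_order[i:j] = order
        self._b_origin[i:j] = origin
        self._b_heading[i:j] = heading
        self._b_tip[i:j] = origin
        self._b_carry[i:j] = 0.0
        self._b_nseg[i:j] = 0
        self._b_base_path[i:j] = base_path
        self._b_laterals[i:j] = 0
        self._n_br = j

    def _append_segments(self, branches: np.ndarray) -> None:
        """Append one segment to each listed branch and spawn laterals.

        ``branches`` must be sorted branch indices; one uniform draw is
        consumed per listed branch (in index order) so the stochastic
        branching decisions are reproducible regardless of how the caller
        batches the appends.
        """
        g = self.genotype
        c = self.constants
        L = c.segment_length
        k = len(branches)
        u = self._b_heading[branches]
        d = u + g.gravitrop * _DOWN
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        start = self._b_tip[branches].copy()
        end = start + L * d
        nseg_before = self._b_nseg[branches]
        path = self._b_base_path[branches] + nseg_before * L
        order = self._b_order[branches]

        self._grow_seg_arrays(k)
        i, j = self._n_seg, self._n_seg + k
        self._s_start[i:j] = start
        self._s_end[i:j] = end
        self._s_branch[i:j] = branches
        self._s_order[i:j] = order
        self._s_path[i:j] = path
        self._s_voxel[i:j] = locate_voxels_flat((start + end) / 2.0, self.soil_params)
        self._s_disc[i:j] = (1.0 - c.water_trans_efficiency) ** path
        self._n_seg = j

        self._b_heading[branches] = d
        self._b_tip[branches] = end
        self._b_nseg[branches] = nseg_before + 1

        # lateral initiation at the junction where the new segment attaches
        # (interior junctions only: the branch already had >= 1 segment)
        draws = self.rng.random(k)
        dist = nseg_before * L  # junction distance along the branch
        prob = np.where(dist <= g.basezonelength, g.basezonep, c.branch_probability)
        spawn = (nseg_before >= 1) & (order < g.maxorder) & (draws < prob)
        if spawn.any():
            parents = branches[spawn]
            axis = d[spawn]
            phase = self._b_laterals[parents] * g.rotang
            lateral = _lateral_headings(axis, phase, g.branchang)
            self._add_branches(
                parent=parents,
                order=order[spawn] + 1,
                origin=start[spawn],
                heading=lateral,
                base_path=path[spawn],
            )
            self._b_laterals[parents] += 1

    # ----------------------------------------------------------------- growth
    def grow(self, root_budget: float) -> None:
        """Spend the day's root biomass budget on elongation and branching."""
        if root_budget < 0:
            raise ValueError("root budget must be >= 0")
        c = self.constants
        L = c.segment_length
        cost = c.segment_cost
        B = self._n_br
        demand_bio = np.full(B, c.max_elongation_rate * cost / L)
        weights = np.power(float(self.genotype.orderweightings), self._b_order[:B].astype(float))
        funded_bio = _share_budget(root_budget, demand_bio, weights)
        carry = self._b_carry[:B] + funded_bio * (L / cost)
        # guard the floor against float round-off in the biomass<->length trip
        n_new = np.floor(carry / L + 1e-9).astype(np.int64)
        self._b_carry[:B] = np.maximum(carry - n_new * L, 0.0)
        for r in range(int(n_new.max()) if B else 0):
            idx = np.nonzero(n_new > r)[0]
            self._append_segments(idx)


def _lateral_headings(axis: np.ndarray, phase: np.ndarray, branchang: float) -> np.ndarray:
    """Initial headings of laterals inserted on parent axes.

    The heading is the parent axis tilted by ``branchang`` towards a
    perpendicular direction whose azimuth advances by the phyllotactic
    phase.  The reference perpendicular is ``axis x down`` (or the x axis
    when the parent is vertical), rotated about the parent axis by
    ``phase`` radians.
    """
    n = len(axis)
    p0 = np.empty((n, 3))
    p0[:, 0] = axis[:, 1]
    p0[:, 1] = -axis[:, 0]
    p0[:, 2] = 0.0
    norm = np.linalg.norm(p0, axis=1)
    vertical = norm < 1e-9
    p0[vertical] = np.array([1.0, 0.0, 0.0])
    norm[vertical] = 1.0
    p0 /= norm[:, None]
    cosp = np.cos(phase)[:, None]
    sinp = np.sin(phase)[:, None]
    p = p0 * cosp + np.cross(axis, p0) * sinp  # Rodrigues, axis . p0 == 0
    h = np.cos(branchang) * axis + np.sin(branchang) * p
    return h / np.linalg.norm(h, axis=1, keepdims=True)


def _share_budget(budget: float, demands: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Divide a biomass budget among tips proportionally to their weights.

    Shares are capped at each tip's demand; surplus from capped tips is
    redistributed among the still-unfilled tips (water-filling), so the
    division is independent of tip enumeration order and spends
    ``min(budget, total demand)`` exactly.
    """
    alloc = np.zeros_like(demands)
    if budget <= 0 or demands.size == 0:
        return alloc
    total = demands.sum()
    if budget >= total:
        return demands.copy()
    remaining = demands.copy()
    left = budget
    active = remaining > 0
    for _ in range(64):
        if left <= 1e-18 or not active.any():
            break
        w = np.where(active, weights, 0.0)
        wsum = w.sum()
        if wsum <= 0:  # all active weights zero: split equally
            w = active.astype(float)
            wsum = w.sum()
        share = left * w / wsum
        take = np.minimum(share, remaining)
        alloc += take
        remaining -= take
        left -= take.sum()
        new_active = remaining > 1e-15
        if new_active.sum() == active.sum():
            break
        active = new_active
    return alloc


def init_plant(
    genotype: Genotype,
    base,
    constants: ModelConstants | None = None,
    soil_params: SoilParams | None = None,
    rng: np.random.Generator | None = None,
    plant_id: int = 0,
) -> Plant:
    """Initialise a plant: a single order-0 branch with one segment heading
    straight down, zero shoot biomass."""
    constants = constants if constants is not None else ModelConstants()
    soil_params = soil_params if soil_params is not None else SoilParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    return Plant(plant_id, genotype, base, constants, soil_params, rng)


def water_demands(plant: Plant, constants: ModelConstants | None = None):
    """Per-segment demands: ``(voxel index triple, demand mm^3, segment id)``.

    Segments whose midpoint lies below the world floor demand nothing and
    are omitted.  Every in-world segment demands the same constant volume
    ``water_uptake_per_root_length * segment_length``.
    """
    constants = constants if constants is not None else plant.constants
    p = plant.soil_params
    demand = constants.segment_demand
    out = []
    for sid, flat in enumerate(plant.seg_voxel):
        if flat == OUTSIDE:
            continue
        iz = flat % p.nz
        iy = (flat // p.nz) % p.ny
        ix = flat // (p.nz * p.ny)
        out.append(((int(ix), int(iy), int(iz)), demand, sid))
    return out


def delivered_water(realized, plant: Plant, constants: ModelConstants | None = None) -> float:
    """Water reaching the base: per-segment uptake x transport discount.

    The discount is ``(1 - water_trans_efficiency) ** path_length_mm``; with
    zero transport loss this is the plain sum over segments.
    """
    realized = np.asarray(realized, dtype=float)
    if realized.size and realized.min() < 0:
        raise ValueError("realized uptake must be >= 0")
    return float(realized @ plant.seg_discount[: realized.size])


def grow_roots(
    plant: Plant,
    root_budget: float,
    rng: np.random.Generator | None = None,
    constants: ModelConstants | None = None,
) -> Plant:
    """Functional wrapper over :meth:`Plant.grow` (optionally overriding the
    plant's RNG stream for the branching draws)."""
    if rng is not None:
        plant.rng = rng
    plant.grow(root_budget)
    return plant
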