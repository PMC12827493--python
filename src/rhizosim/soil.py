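"""Voxelized soil water balance: recharge, evaporation, diffusion, uptake.

The soil is a lattice of cubic voxels, ``nx`` x ``ny`` x ``nz``, with the z
axis pointing *down* from the surface (layer ``z = 0`` is the top).  Each
voxel holds a water volume bounded by its capacity ``side^3 x whc``.
Horizontal boundaries are toroidal (wrap-around) for both diffusion and root
placement; there is no flux through the top or bottom face.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SoilParams",
    "SoilGrid",
    "voxel_capacity",
    "locate_voxel",
    "recharge",
    "evaporate",
    "diffuse",
    "extract",
    "OUTSIDE",
]

#: Sentinel flat voxel index for positions below the world floor / above it.
OUTSIDE = -1


@dataclass(frozen=True)
class SoilParams:
    """Geometry and water parameters of the voxel world."""

    nx: int = 10
    ny: int = 10
    nz: int = 70
    voxel_side: float = 20.0  # mm
    whc: float = 0.1  # water-holding capacity, fraction of voxel volume
    diffuse_per_day: float = 0.1  # diffusible fraction of voxel water per day
    evaporation_rate: float = 0.5  # top-layer fractional loss per day
    recharge_interval: int = 1  # days between full recharges

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be >= 1")
        if self.voxel_side <= 0:
            raise ValueError("voxel_side must be positive")
        for name in ("whc", "diffuse_per_day", "evaporation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.recharge_interval < 1:
            raise ValueError("recharge_interval must be >= 1")

    @property
    def extent_x(self) -> float:
        """Horizontal world extent along x (mm)."""
        return self.nx * self.voxel_side

    @property
    def extent_y(self) -> float:
        return self.ny * self.voxel_side

    @property
    def depth(self) -> float:
        """World depth (mm)."""
        return self.nz * self.voxel_side

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz


def voxel_capacity(params: SoilParams) -> float:
    """Maximum water volume one voxel can hold (mm^3)."""
    return params.voxel_side**3 * params.whc


class SoilGrid:
    """Per-voxel water volumes on the voxel lattice.

    Water is stored as a flat float array of length ``nx*ny*nz`` in C order
    of ``(x, y, z)``; ``water3d`` exposes the cubic view.  A fresh grid
    starts at full capacity.
    """

    def __init__(self, params: SoilParams | None = None, water: np.ndarray | None = None):
        self.params = params if params is not None else SoilParams()
        cap = voxel_capacity(self.params)
        if water is None:
            self.water = np.full(self.params.n_voxels, cap, dtype=float)
        else:
            water = np.asarray(water, dtype=float).reshape(-1)
            if water.size != self.params.n_voxels:
                raise ValueError("water array size mismatch")
            if water.min() < -1e-12 or water.max() > cap * (1 + 1e-12):
                raise ValueError("water outside [0, capacity]")
            self.water = water.copy()

    @property
    def capacity(self) -> float:
        return voxel_capacity(self.params)

    @property
    def water3d(self) -> np.ndarray:
        p = self.params
        return self.water.reshape(p.nx, p.ny, p.nz)

    def total_water(self) -> float:
        return float(self.water.sum())

    def copy(self) -> "SoilGrid":
        return SoilGrid(self.params, self.water)

    def to_frame(self) -> pd.DataFrame:
        """Long-format snapshot: one row per voxel (x, y, z, water_mm3)."""
        p = self.params
        x, y, z = np.unravel_index(np.arange(p.n_voxels), (p.nx, p.ny, p.nz))
        return pd.DataFrame({"x": x, "y": y, "z": z, "water_mm3": self.water})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def locate_voxel(position: Sequence[float], params: SoilParams) -> tuple[int, int, int] | None:
    """Map a world-coordinate point (mm) to its voxel index.

    x and y wrap around the horizontal extent; returns ``None`` when the
    point lies above the surface (z < 0) or below the world floor.
    Voxels are half-open ``[k*side, (k+1)*side)`` per axis.
    """
    x, y, z = position
    if z < 0 or z >= params.depth:
        return None
    side = params.voxel_side
    ix = int(np.floor((x % params.extent_x) / side)) % params.nx
    iy = int(np.floor((y % params.extent_y) / side)) % params.ny
    iz = int(np.floor(z / side))
    return ix, iy, iz


def locate_voxels_flat(points: np.ndarray, params: SoilParams) -> np.ndarray:
    """Vectorized point -> flat voxel index; ``OUTSIDE`` below/above world."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    side = params.voxel_side
    ix = np.floor(np.mod(points[:, 0], params.extent_x) / side).astype(np.int64) % params.nx
    iy = np.floor(np.mod(points[:, 1], params.extent_y) / side).astype(np.int64) % params.ny
    iz = np.floor(points[:, 2] / side).astype(np.int64)
    flat = (ix * params.ny + iy) * params.nz + iz
    outside = (points[:, 2] < 0) | (iz >= params.nz)
    flat[outside] = OUTSIDE
    return flat


def recharge(grid: SoilGrid, day: int) -> SoilGrid:
    """Refill every voxel to capacity when ``day`` hits the recharge interval."""
    if day < 0:
        raise ValueError("day must be >= 0")
    if day % grid.params.recharge_interval == 0:
        grid.water[:] = grid.capacity
    return grid


def evaporate(grid: SoilGrid) -> SoilGrid:
    """Remove a fraction of the water from the top voxel layer only."""
    p = grid.params
    w = grid.water3d
    w[:, :, 0] *= 1.0 - p.evaporation_rate
    return grid


def diffuse(grid: SoilGrid) -> SoilGrid:
    """One synchronous diffusion step.

    Each voxel stages ``water * diffuse_per_day`` for diffusion and sends
    1/6 of that to each face neighbour.  Horizontal neighbours wrap around;
    the would-be flux through the top face of layer 0 and the bottom face
    of the last layer stays in the source voxel.  Outflows are computed
    from the pre-step state (Jacobi update), so total water is conserved
    exactly and the result does not depend on voxel enumeration order.
    """
    p = grid.params
    w = grid.water3d
    out = w * (p.diffuse_per_day / 6.0)  # per-face outgoing flux

    new = w.copy()
    # losses: 6 faces minus the blocked vertical faces
    faces = np.full(p.nz, 6.0)
    faces[0] -= 1.0
    faces[-1] -= 1.0  # nz == 1 leaves both vertical faces blocked
    new -= out * faces
    # horizontal gains with wraparound
    new += np.roll(out, 1, axis=0) + np.roll(out, -1, axis=0)
    new += np.roll(out, 1, axis=1) + np.roll(out, -1, axis=1)
    # vertical gains, no wrap
    if p.nz > 1:
        new[:, :, 1:] += out[:, :, :-1]
        new[:, :, :-1] += out[:, :, 1:]
    grid.water[:] = new.reshape(-1)
    return grid


def extract_pooled(
    grid: SoilGrid, voxel_flat: np.ndarray, demands: np.ndarray
) -> np.ndarray:
    """Satisfy per-segment demands with proportional rationing per voxel.

    All claimants in a voxel — regardless of which plant they belong to —
    share the available water proportionally to their demand when the voxel
    cannot cover the total.  Entries with voxel index ``OUTSIDE`` receive
    nothing.  Returns realized uptake aligned with the input order and
    decrements the grid in place.
    """
    voxel_flat = np.asarray(voxel_flat)
    demands = np.asarray(demands, dtype=float)
    if demands.size and demands.min() < 0:
        raise ValueError("negative demand: invalid root state")
    realized = np.zeros_like(demands)
    inside = voxel_flat >= 0
    if not inside.any():
        return realized
    vox = voxel_flat[inside]
    dem = demands[inside]
    total = np.bincount(vox, weights=dem, minlength=grid.water.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, np.minimum(1.0, grid.water / total), 0.0)
    realized[inside] = dem * frac[vox]
    grid.water -= np.minimum(total, np.where(total > 0, grid.water, 0.0))
    np.maximum(grid.water, 0.0, out=grid.water)
    return realized


def extract(grid: SoilGrid, demands) -> list[float]:
    """List-interface wrapper over :func:`extract_pooled`.

    ``demands`` is a sequence of ``(voxel index, demand mm^3, claimant id)``
    where the voxel index is an ``(ix, iy, iz)`` triple.  Returns realized
    uptake per entry, in input order.
    """
    p = grid.params
    if not demands:
        return []
    flat = np.array(
        [(ix * p.ny + iy) * p.nz + iz for (ix, iy, iz), _, _ in demands],
        dtype=np.int64,
    )
    vols = np.array([d for _, d, _ in demands], dtype=float)
    return extract_pooled(grid, flat, vols).tolist()
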