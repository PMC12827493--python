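"""Emergent root-morphology metrics and their PCA summary.

Seven whole-root-system measures computed on a final plant structure:
maximum horizontal reach, depth, root biomass, length per biomass,
branches per length, biomass density per occupied voxel, and the
box-counting fractal dimension of the root skeleton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .plant import Plant
from .soil import OUTSIDE, SoilParams

__all__ = [
    "MorphologyRecord",
    "morphology",
    "box_counting_dimension",
    "morphology_pca",
    "records_frame",
]

#: Default dyadic box sides for the box-counting fit (mm).
DEFAULT_SCALES = (40.0, 20.0, 10.0, 5.0)


@dataclass(frozen=True)
class MorphologyRecord:
    max_horizontal_length: float  # mm, furthest segment endpoint from the base
    root_depth: float  # mm, deepest segment endpoint
    root_biomass: float  # g
    length_per_biomass: float  # mm g^-1
    branches_per_length: float  # mm^-1
    density_per_voxel: float  # g voxel^-1, biomass / occupied voxel count
    fractal_dimension: float  # box-counting slope, in [0, 3]

    def to_dict(self) -> dict:
        return asdict(self)


def _raster_points(seg_start: np.ndarray, seg_end: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Sample points every ``step`` mm along each segment (at step midpoints,
    so consecutive segments do not double-count their shared junction)."""
    lengths = np.linalg.norm(seg_end - seg_start, axis=1)
    n_steps = np.maximum(1, np.round(lengths / step).astype(int))
    reps = np.repeat(np.arange(len(lengths)), n_steps)
    # fractional positions (i + 0.5) / n within each segment
    offsets = np.concatenate([np.arange(n) for n in n_steps]) + 0.5
    frac = offsets / n_steps[reps]
    return seg_start[reps] + frac[:, None] * (seg_end[reps] - seg_start[reps])


def box_counting_dimension(
    seg_start: np.ndarray,
    seg_end: np.ndarray,
    scales: Sequence[float] = DEFAULT_SCALES,
    step: float = 1.0,
) -> tuple[float, float]:
    """Box-counting fractal dimension of a segment skeleton.

    Segments are rasterized into points every ``step`` mm; for each box
    side ``s`` the occupied axis-aligned cubes are counted, and the
    dimension is the negative slope of the least-squares line of
    ``log N(s)`` against ``log s``.  Returns ``(dimension, r_squared)``.

    Raises ``ValueError`` when the structure occupies a single box at
    every scale (the slope is undefined).
    """
    seg_start = np.asarray(seg_start, dtype=float).reshape(-1, 3)
    seg_end = np.asarray(seg_end, dtype=float).reshape(-1, 3)
    if len(seg_start) == 0:
        raise ValueError("empty structure")
    pts = _raster_points(seg_start, seg_end, step)
    pts = pts - pts.min(axis=0)  # anchor the box lattice at the structure
    counts = []
    for s in scales:
        boxes = np.floor(pts / s).astype(np.int64)
        counts.append(len(np.unique(boxes, axis=0)))
    counts = np.array(counts, dtype=float)
    if counts.max() < 2:
        raise ValueError("degenerate structure: one occupied box at every scale")
    fit = stats.linregress(np.log(np.asarray(scales, dtype=float)), np.log(counts))
    return float(-fit.slope), float(fit.rvalue**2)


def morphology(plant: Plant, soil_params: SoilParams | None = None) -> MorphologyRecord:
    """Compute the seven morphology metrics for one plant.

    Horizontal reach and depth use unwrapped world coordinates relative to
    the plant base, so they are invariant to horizontal translation of the
    whole plant through the toroidal world.
    """
    if plant.n_segments < 1:
        raise ValueError("plant has no root segments")
    ends = plant.seg_end
    rel = ends - plant.base
    max_horizontal = float(np.sqrt(rel[:, 0] ** 2 + rel[:, 1] ** 2).max())
    depth = float(rel[:, 2].max())
    biomass = plant.root_biomass
    total_length = plant.n_segments * plant.constants.segment_length
    inside = plant.seg_voxel[plant.seg_voxel != OUTSIDE]
    occupied = len(np.unique(inside)) if inside.size else 1
    try:
        dim, _ = box_counting_dimension(plant.seg_start, plant.seg_end)
    except ValueError:
        dim = float("nan")  # degenerate skeleton: slope undefined
    return MorphologyRecord(
        max_horizontal_length=max_horizontal,
        root_depth=depth,
        root_biomass=biomass,
        length_per_biomass=total_length / biomass,
        branches_per_length=plant.n_branches / total_length,
        density_per_voxel=biomass / occupied,
        fractal_dimension=dim,
    )


def records_frame(records: Sequence[MorphologyRecord], **extra_columns) -> pd.DataFrame:
    """Stack morphology records into a tidy DataFrame (plus label columns)."""
    df = pd.DataFrame([r.to_dict() for r in records])
    for name, values in extra_columns.items():
        df[name] = values
    return df


@dataclass
class PcaSummary:
    scores: pd.DataFrame  # per-plant coordinates on PC1, PC2
    loadings: pd.DataFrame  # metric loadings per retained PC
    explained_variance_ratio: np.ndarray
    dropped_columns: list[str]


def morphology_pca(records: pd.DataFrame, standardize: bool = True, n_components: int | None = None) -> PcaSummary:
    """PCA of the (standardized) morphology metrics across plants.

    Constant metric columns are dropped with a warning.  Sign convention:
    each component is flipped so its largest-magnitude loading is positive.
    """
    metrics = records.select_dtypes(include=[np.number])
    if len(metrics) < 3:
        raise ValueError("need at least 3 records")
    sd = metrics.std(axis=0, ddof=0)
    scale = metrics.abs().mean(axis=0).clip(lower=1.0)
    dropped = list(metrics.columns[sd <= 1e-9 * scale])  # constant up to round-off
    if dropped:
        warnings.warn(f"dropping constant metric columns: {dropped}")
        metrics = metrics.drop(columns=dropped)
    if metrics.shape[1] < 2:
        raise ValueError("need at least 2 metrics with nonzero variance")
    X = metrics.to_numpy(dtype=float)
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    k = n_components if n_components is not None else min(X.shape)
    pca = PCA(n_components=min(k, min(X.shape)))
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # sign convention: dominant loading of each PC positive
    for j in range(loadings.shape[0]):
        i = np.argmax(np.abs(loadings[j]))
        if loadings[j, i] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    pc_names = [f"PC{j + 1}" for j in range(loadings.shape[0])]
    return PcaSummary(
        scores=pd.DataFrame(scores, columns=pc_names, index=records.index),
        loadings=pd.DataFrame(loadings, columns=metrics.columns, index=pc_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_columns=dropped,
    )
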