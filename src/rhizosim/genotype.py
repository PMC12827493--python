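"""Evolvable root-architecture genotypes.

A genotype is the set of nine architecture parameters that stay fixed for a
plant's lifetime but evolve across generations: the phyllotactic rotation
between successive laterals (``rotang``), the insertion angle of a lateral
away from its parent axis (``branchang``), the strength of the downward
gravitropic pull (``gravitrop``), the length of the basal zone within which
lateral initiation is probabilistic (``basezonelength``) and that probability
(``basezonep``), the maximum branching order (``maxorder``), the growth
priority exponent per branching order (``orderweightings``), and the two
shoot-allocation coefficients (``kshoot1``, ``kshoot2``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from typing import Mapping

import numpy as np

__all__ = [
    "Genotype",
    "PARAM_NAMES",
    "SAMPLING_RANGES",
    "HARD_LIMITS",
    "sample_genotype",
    "genotype_matrix",
]

#: Canonical parameter order; also the JSON serialization keys.
PARAM_NAMES = (
    "rotang",
    "branchang",
    "gravitrop",
    "basezonelength",
    "basezonep",
    "maxorder",
    "orderweightings",
    "kshoot1",
    "kshoot2",
)

#: Initial-value sampling ranges used to seed evolutionary populations.
SAMPLING_RANGES: Mapping[str, tuple[float, float]] = {
    "rotang": (0.0, 1.5),
    "branchang": (0.0, 1.5),
    "gravitrop": (0.0, 0.3),
    "basezonelength": (5.0, 30.0),
    "basezonep": (0.0, 1.0),
    "maxorder": (2.0, 8.0),
    "orderweightings": (0.5, 2.0),
    "kshoot1": (-5.0, 5.0),
    "kshoot2": (-0.1, 0.03),
}

#: Hard limits enforced at construction and after mutation.  ``None`` means
#: unbounded on that side.
HARD_LIMITS: Mapping[str, tuple[float | None, float | None]] = {
    "rotang": (None, None),
    "branchang": (None, None),
    "gravitrop": (0.0, None),
    "basezonelength": (0.0, None),
    "basezonep": (0.0, 1.0),
    "maxorder": (2.0, 9.0),
    "orderweightings": (0.0, None),
    "kshoot1": (None, None),
    "kshoot2": (None, None),
}


@dataclass(frozen=True)
class Genotype:
    """One set of architecture parameter values; the unit of selection."""

    rotang: float  # radians, phyllotactic rotation between laterals
    branchang: float  # radians, lateral insertion angle off the parent axis
    gravitrop: float  # downward pull added per new segment (dimensionless)
    basezonelength: float  # mm of branch base with probabilistic branching
    basezonep: float  # branching probability within the base zone
    maxorder: int  # maximum branching order, 2..9
    orderweightings: float  # growth-priority base, weight = ow**order
    kshoot1: float  # shoot-allocation intercept
    kshoot2: float  # shoot-allocation slope per mg of allocable biomass

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(float(value)):
                raise ValueError(f"{name} must be finite, got {value!r}")
            lo, hi = HARD_LIMITS[name]
            if lo is not None and value < lo:
                raise ValueError(f"{name}={value} below limit {lo}")
            if hi is not None and value > hi:
                raise ValueError(f"{name}={value} above limit {hi}")
        if int(self.maxorder) != self.maxorder:
            raise ValueError(f"maxorder must be an integer, got {self.maxorder}")
        object.__setattr__(self, "maxorder", int(self.maxorder))

    def as_vector(self) -> np.ndarray:
        """Parameter values in :data:`PARAM_NAMES` order (maxorder as float)."""
        return np.array([float(getattr(self, n)) for n in PARAM_NAMES])

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, record: Mapping[str, float]) -> "Genotype":
        return cls(**{n: record[n] for n in PARAM_NAMES})

    @classmethod
    def from_json(cls, text: str) -> "Genotype":
        return cls.from_dict(json.loads(text))

    def replace(self, **changes) -> "Genotype":
        return replace(self, **changes)


def clip_to_limits(name: str, value: float) -> float:
    """Clip a raw parameter value into its hard limits; round ``maxorder``."""
    lo, hi = HARD_LIMITS[name]
    if lo is not None:
        value = max(lo, value)
    if hi is not None:
        value = min(hi, value)
    if name == "maxorder":
        value = float(int(round(value)))
        value = min(max(value, 2.0), 9.0)
    return value


def sample_genotype(rng: np.random.Generator) -> Genotype:
    """Draw a random genotype uniformly from the initial sampling ranges.

    ``maxorder`` is drawn uniformly on its continuous range and rounded to
    the nearest integer.
    """
    values = {}
    for name in PARAM_NAMES:
        lo, hi = SAMPLING_RANGES[name]
        v = rng.uniform(lo, hi)
        values[name] = clip_to_limits(name, v)
    values["maxorder"] = int(values["maxorder"])
    return Genotype(**values)


def genotype_matrix(genotypes) -> np.ndarray:
    """Stack genotypes into an (n, 9) parameter matrix in canonical order."""
    return np.vstack([g.as_vector() for g in genotypes])
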