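"""Model constants shared by every plant and generation.

These are the non-evolving physical and physiological parameters of the
model: conversion efficiencies, uptake and elongation rates, and segment
geometry.  Defaults are the study's standard values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ModelConstants"]


@dataclass(frozen=True)
class ModelConstants:
    """Non-evolvable constants of the plant/soil model.

    Attributes
    ----------
    water_to_biomass:
        Biomass obtained per volume of water taken up (g mm^-3).
    biomass_per_volume:
        Biomass per unit of root tissue volume (g mm^-3).
    water_trans_efficiency:
        Per-mm fractional loss of water transported from a root segment to
        the plant base; applied as a multiplicative discount
        ``(1 - c) ** path_length_mm``.  Zero recovers a lossless sum.
    water_uptake_per_root_length:
        Potential water uptake per mm of root length per day (mm^3 mm^-1).
    max_elongation_rate:
        Maximum daily elongation per branch tip (mm day^-1).
    segment_length:
        Length of one root segment (mm).
    root_radius:
        Radius of the root cylinder used to cost a segment (mm).
    branch_probability:
        Probability of lateral initiation at a junction beyond the base
        zone (within the base zone the genotype's ``basezonep`` applies).
    """

    water_to_biomass: float = 0.00001
    biomass_per_volume: float = 0.001
    water_trans_efficiency: float = 0.002
    water_uptake_per_root_length: float = 10.0
    max_elongation_rate: float = 5.0
    segment_length: float = 2.0
    root_radius: float = 0.5
    branch_probability: float = 1.0

    def __post_init__(self) -> None:
        positive = (
            "water_to_biomass",
            "biomass_per_volume",
            "water_uptake_per_root_length",
            "max_elongation_rate",
            "segment_length",
            "root_radius",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.water_trans_efficiency < 1.0:
            raise ValueError("water_trans_efficiency must lie in [0, 1)")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must lie in [0, 1]")

    @property
    def segment_cost(self) -> float:
        """Biomass cost of one segment: cylinder volume x biomass density (g)."""
        return (
            math.pi
            * self.root_radius**2
            * self.segment_length
            * self.biomass_per_volume
        )

    @property
    def segment_demand(self) -> float:
        """Potential daily water demand of one segment (mm^3)."""
        return self.water_uptake_per_root_length * self.segment_length
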