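"""Exports: flat segment CSV, RSML root structures, genotype JSON records,
biomass time series, and soil-grid snapshots."""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype import Genotype, PARAM_NAMES
from .plant import Plant
from .simulate import SimulationResult

__all__ = [
    "segments_frame",
    "write_segments_csv",
    "write_rsml",
    "write_genotypes_json",
    "read_genotypes_json",
    "biomass_frame",
    "write_biomass_csv",
]


def segments_frame(plants: Sequence[Plant]) -> pd.DataFrame:
    """One tidy table of segments across plants."""
    return pd.concat([p.segments_frame() for p in plants], ignore_index=True)


def write_segments_csv(plants: Sequence[Plant], path) -> None:
    segments_frame(plants).to_csv(path, index=False)


def write_rsml(plant: Plant, path) -> None:
    """Write one plant's root system as RSML (polyline geometry per root,
    laterals nested under their parent root)."""
    rsml = ET.Element("rsml")
    meta = ET.SubElement(rsml, "metadata")
    ET.SubElement(meta, "unit").text = "mm"
    ET.SubElement(meta, "software").text = "rhizosim"
    scene = ET.SubElement(rsml, "scene")
    plant_el = ET.SubElement(scene, "plant", id=str(plant.id))

    children: dict[int, list[int]] = {}
    for b in range(plant.n_branches):
        parent = int(plant.branch_parent[b])
        children.setdefault(parent, []).append(b)

    seg_branch = plant.seg_branch
    starts, ends = plant.seg_start, plant.seg_end

    def emit(branch: int, into: ET.Element) -> None:
        root_el = ET.SubElement(into, "root", id=str(branch), label=f"order{int(plant.branch_order[branch])}")
        geom = ET.SubElement(root_el, "geometry")
        line = ET.SubElement(geom, "polyline")
        mask = seg_branch == branch
        pts = np.vstack([starts[mask][:1], ends[mask]]) if mask.any() else np.empty((0, 3))
        for p in pts:
            ET.SubElement(line, "point", x=f"{p[0]:.4f}", y=f"{p[1]:.4f}", z=f"{p[2]:.4f}")
        for child in children.get(branch, []):
            emit(child, root_el)

    for top in children.get(-1, []):
        emit(top, plant_el)
    ET.ElementTree(rsml).write(path, xml_declaration=True, encoding="unicode")


def write_genotypes_json(genotypes: Sequence[Genotype], path) -> None:
    with open(path, "w") as fh:
        json.dump([g.to_dict() for g in genotypes], fh, indent=1)


def read_genotypes_json(path) -> list[Genotype]:
    with open(path) as fh:
        records = json.load(fh)
    return [Genotype(**{n: r[n] for n in PARAM_NAMES}) for r in records]


def biomass_frame(result: SimulationResult) -> pd.DataFrame:
    """Long-format daily biomass: plant_id, day, shoot_g, root_g."""
    n, days = result.shoot.shape
    rows = []
    for i in range(n):
        for d in range(days):
            rows.append((i, d, result.shoot[i, d], result.root[i, d]))
    return pd.DataFrame(rows, columns=["plant_id", "day", "shoot_g", "root_g"])


def write_biomass_csv(result: SimulationResult, path) -> None:
    biomass_frame(result).to_csv(path, index=False)
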