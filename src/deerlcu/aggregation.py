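"""Zonal aggregation of habitat quality scores into per-unit LCU values.

A unit's LCU for one land-cover year is the sum of the per-cell quality
scores of the cells whose centers fall inside the unit, divided by the
unit's total area in km² (the declared polygon area, not habitat area).
Units come in three nested levels — section (TRS), township, county — and
may be defined by a polygon in the raster CRS or an explicit cell mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

LEVELS = ("TRS", "TOWNSHIP", "COUNTY")

LCU_COLUMNS = ["unit_id", "level", "year", "lcu", "score_sum", "n_cells"]


@dataclass(frozen=True)
class SpatialUnit:
    """One spatial unit: polygon- or mask-defined, with a declared area."""

    unit_id: str
    level: str
    area_km2: float
    geometry: BaseGeometry | None = None
    mask: np.ndarray | None = None
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if self.area_km2 <= 0:
            raise ValueError(f"unit {self.unit_id}: area_km2 must be positive")
        if (self.geometry is None) == (self.mask is None):
            raise ValueError(
                f"unit {self.unit_id}: exactly one of geometry or mask required"
            )


@dataclass
class SpatialUnitSet:
    """Collection of spatial units across the three nested levels."""

    units: list[SpatialUnit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def levels(self) -> list[str]:
        present = {u.level for u in self.units}
        return [lv for lv in LEVELS if lv in present]

    def at_level(self, level: str) -> list[SpatialUnit]:
        return [u for u in self.units if u.level == level]

    def by_id(self, unit_id: str) -> SpatialUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "SpatialUnitSet":
        """Load units from a GeoJSON FeatureCollection.

        Each feature needs properties ``unit_id`` and ``level``;
        ``area_km2`` and ``parent`` are optional (area defaults to the
        polygon area assuming meter coordinates).
        """
        data = json.loads(Path(path).read_text())
        units = []
        for feat in data["features"]:
            props = feat.get("properties", {})
            geom = shapely_shape(feat["geometry"])
            area = props.get("area_km2")
            if area is None:
                area = geom.area / 1e6
            units.append(
                SpatialUnit(
                    unit_id=str(props["unit_id"]),
                    level=props["level"],
                    area_km2=float(area),
                    geometry=geom,
                    parent=props.get("parent"),
                )
            )
        return cls(units)

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for u in self.units:
            if u.geometry is None:
                raise ValueError(f"unit {u.unit_id} is mask-based; cannot serialize")
            props = {"unit_id": u.unit_id, "level": u.level, "area_km2": u.area_km2}
            if u.parent is not None:
                props["parent"] = u.parent
            features.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": shapely_mapping(u.geometry),
                }
            )
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )


def assign_cells_to_units(grid, units: SpatialUnitSet, level: str) -> np.ndarray:
    """Map each cell to the unit (at one level) containing its center.

    Returns an integer grid indexing into ``units.at_level(level)``; −1
    marks unassigned cells.  A cell strictly inside two units is an error.
    Centers on a shared boundary go to the unit whose bounding box has the
    smallest (min-y, min-x) — the lower-left unit wins.
    """
    level_units = units.at_level(level)
    if not level_units:
        raise ValueError(f"no units at level {level!r}")
    cx, cy = grid.cell_centers()
    out = np.full(grid.shape, -1, dtype=np.int64)

    if all(u.mask is not None for u in level_units):
        overlap = np.zeros(grid.shape, dtype=np.int64)
        for idx, u in enumerate(level_units):
            if u.mask.shape != grid.shape:
                raise ValueError(f"unit {u.unit_id}: mask shape differs from grid")
            overlap += u.mask.astype(np.int64)
            out[u.mask] = idx
        if (overlap > 1).any():
            raise ValueError(f"overlapping unit masks at level {level}")
        return out

    x = cx.ravel()
    y = cy.ravel()
    flat = out.ravel()
    inside_count = np.zeros(x.size, dtype=np.int64)
    order = sorted(
        range(len(level_units)),
        key=lambda i: (level_units[i].geometry.bounds[1], level_units[i].geometry.bounds[0]),
    )
    for idx in order:
        geom = level_units[idx].geometry
        shapely.prepare(geom)
        inside_count += shapely.contains_xy(geom, x, y)
        hit = shapely.intersects_xy(geom, x, y) & (flat == -1)
        flat[hit] = idx
    if (inside_count > 1).any():
        raise ValueError(
            f"overlapping units at level {level}: a cell center lies strictly "
            "inside more than one unit"
        )
    return flat.reshape(grid.shape)


def compute_lcu(
    scores,
    units: SpatialUnitSet,
    levels: Sequence[str] | None = None,
    membership: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Aggregate a score grid into one LCU row per (unit, year).

    ``lcu = score_sum / area_km2`` with score_sum the exact sum of member
    cells' scores; units containing no habitat simply get 0.
    """
    levels = list(levels) if levels is not None else units.levels()
    rows = []
    for level in levels:
        level_units = units.at_level(level)
        member = (
            membership[level]
            if membership is not None and level in membership
            else assign_cells_to_units(scores, units, level)
        )
        flat_member = member.ravel()
        # scores are multiples of 0.2; summing 5x-scaled integers keeps
        # score sums exact (children add up to parents bit-for-bit)
        flat_fifths = np.rint(scores.scores.ravel() * 5.0).astype(np.int64)
        valid = flat_member >= 0
        sums = (
            np.bincount(
                flat_member[valid],
                weights=flat_fifths[valid],
                minlength=len(level_units),
            )
            / 5.0
        )
        counts = np.bincount(flat_member[valid], minlength=len(level_units))
        for idx, unit in enumerate(level_units):
            rows.append(
                {
                    "unit_id": unit.unit_id,
                    "level": level,
                    "year": scores.year_label,
                    "lcu": sums[idx] / unit.area_km2,
                    "score_sum": sums[idx],
                    "n_cells": int(counts[idx]),
                }
            )
    df = pd.DataFrame(rows, columns=LCU_COLUMNS)
    return df.sort_values(["level", "unit_id", "year"], ignore_index=True)


#: Alias documenting the tabular contract of :func:`compute_lcu`.
LCUTable = pd.DataFrame


def write_lcu_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an LCU table as CSV with a stable (level, unit_id, year) order."""
    missing = [c for c in LCU_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"LCU table missing columns: {missing}")
    out = table[LCU_COLUMNS].sort_values(["level", "unit_id", "year"])
    out.to_csv(path, index=False, float_format="%.17g")


def read_lcu_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str})
    missing = [c for c in LCU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"LCU table missing columns: {missing}")
    return df


def check_nesting(units: SpatialUnitSet, membership: dict[str, np.ndarray]) -> bool:
    """True iff every child's cells are a subset of its parent's cells."""
    child_parent = {"TRS": "TOWNSHIP", "TOWNSHIP": "COUNTY"}
    for child_level, parent_level in child_parent.items():
        if child_level not in membership or parent_level not in membership:
            continue
        child_units = units.at_level(child_level)
        parent_ids = [u.unit_id for u in units.at_level(parent_level)]
        for idx, child in enumerate(child_units):
            if child.parent is None:
                continue
            cells = membership[child_level] == idx
            parent_idx = parent_ids.index(child.parent)
            if not np.all(membership[parent_level][cells] == parent_idx):
                return False
    return True
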