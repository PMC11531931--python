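"""Categorical land-cover rasters and habitat-group remapping.

Rasters are represented as plain 2-D integer arrays with a minimal
georeference: a square cell size in meters and the projected coordinates of
the top-left corner.  Two on-disk formats are supported: ESRI-style ASCII
grids (no extra dependencies, used throughout the test suite) and
single-band GeoTIFF (requires the optional ``rasterio`` dependency).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: NLCD 2001–2021 class codes (legend names for reference).
NLCD_VOCABULARY = {
    11: "Open water",
    21: "Developed, open space",
    22: "Developed, low intensity",
    23: "Developed, medium intensity",
    24: "Developed, high intensity",
    31: "Barren land",
    41: "Deciduous forest",
    42: "Evergreen forest",
    43: "Mixed forest",
    52: "Shrub/scrub",
    71: "Grassland/herbaceous",
    81: "Pasture/hay",
    82: "Cultivated crops",
    90: "Woody wetlands",
    95: "Emergent herbaceous wetlands",
}


class HabitatGroup(IntEnum):
    """Habitat group assigned to each raster cell."""

    NONE = 0
    SHELTER_FOOD = 1
    FOOD = 2


@dataclass(frozen=True)
class ClassGrid:
    """Single-band categorical land-cover raster.

    Parameters
    ----------
    values
        2-D integer array of land-cover class codes.
    cell_size_m
        Edge length of the (square) cells in meters.
    origin
        ``(x, y)`` projected coordinates of the grid's top-left corner.
    nodata_code
        Code marking cells with no data.
    year_label
        Land-cover release year the raster represents.
    """

    values: np.ndarray
    cell_size_m: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_code: int = -9999
    year_label: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if not np.issubdtype(values.dtype, np.integer):
            raise TypeError(f"class codes must be integers, got dtype {values.dtype}")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected ``(x, y)`` coordinates of every cell center.

        Returns two arrays of the grid's shape; row 0 is the northernmost
        (highest y) row, matching raster conventions.
        """
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size_m
        ys = y0 - (np.arange(nrows) + 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)


@dataclass(frozen=True)
class HabitatGrid:
    """Grid of :class:`HabitatGroup` codes sharing a ClassGrid's georeference."""

    groups: np.ndarray
    cell_size_m: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    year_label: int = 0

    def __post_init__(self) -> None:
        groups = np.asarray(self.groups)
        if groups.ndim != 2 or groups.size == 0:
            raise ValueError("groups must be a non-empty 2-D array")
        valid = np.isin(groups, [g.value for g in HabitatGroup])
        if not valid.all():
            bad = np.unique(groups[~valid])
            raise ValueError(f"invalid habitat group codes: {bad.tolist()}")
        object.__setattr__(self, "groups", groups.astype(np.int8))
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.groups.shape

    def mask(self, group: HabitatGroup) -> np.ndarray:
        return self.groups == int(group)

    cell_centers = ClassGrid.cell_centers


@dataclass(frozen=True)
class ClassMapping:
    """Assignment of land-cover class codes to habitat groups.

    ``no_hunt_classes`` collects the developed and open-water classes used
    for the no-hunt-area covariate; they never overlap the habitat sets.
    """

    shelter_food_classes: frozenset[int]
    food_classes: frozenset[int]
    no_hunt_classes: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        sf = frozenset(int(c) for c in self.shelter_food_classes)
        fo = frozenset(int(c) for c in self.food_classes)
        nh = frozenset(int(c) for c in self.no_hunt_classes)
        if sf & fo:
            raise ValueError(f"classes in both habitat groups: {sorted(sf & fo)}")
        if nh & (sf | fo):
            raise ValueError(
                f"no-hunt classes overlap habitat classes: {sorted(nh & (sf | fo))}"
            )
        object.__setattr__(self, "shelter_food_classes", sf)
        object.__setattr__(self, "food_classes", fo)
        object.__setattr__(self, "no_hunt_classes", nh)

    def group_of(self, code: int) -> HabitatGroup:
        if code in self.shelter_food_classes:
            return HabitatGroup.SHELTER_FOOD
        if code in self.food_classes:
            return HabitatGroup.FOOD
        return HabitatGroup.NONE

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[int]]) -> "ClassMapping":
        return cls(
            shelter_food_classes=frozenset(d.get("shelter_food_classes", ())),
            food_classes=frozenset(d.get("food_classes", ())),
            no_hunt_classes=frozenset(d.get("no_hunt_classes", ())),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ClassMapping":
        """Load a mapping from a YAML or JSON config file."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            import yaml

            data = yaml.safe_load(text)
        return cls.from_dict(data)


def default_nlcd_mapping() -> ClassMapping:
    """Default NLCD class-to-habitat-group assignment.

    Shelter/food: deciduous (41), evergreen (42) and mixed (43) forest plus
    woody (90) and emergent herbaceous (95) wetlands.  Food: shrub/scrub
    (52), grassland/herbaceous (71), pasture/hay (81), cultivated crops
    (82).  No-hunt: the four developed classes (21–24) and open water (11).
    Classes not listed (e.g. barren land, 31) map to ``NONE``.
    """
    return ClassMapping(
        shelter_food_classes=frozenset({41, 42, 43, 90, 95}),
        food_classes=frozenset({52, 71, 81, 82}),
        no_hunt_classes=frozenset({11, 21, 22, 23, 24}),
    )


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    """Parse an ESRI-style ASCII grid.

    Returns ``(values, cellsize, origin_top_left, nodata)`` with values kept
    as floats; callers decide integer coercion.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
        else:
            data_start = i
            break
    missing = [k for k in _ASCII_HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: ASCII grid header missing keys {missing}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    if cellsize <= 0:
        raise ValueError(f"{path}: degenerate cellsize {cellsize}")
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(lines[data_start:], dtype=float, ndmin=2)
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    # ASCII headers give the lower-left corner; convert to top-left origin.
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cellsize)
    return values, cellsize, origin, nodata


def write_ascii_grid(
    values: np.ndarray,
    path: str | Path,
    cell_size_m: float,
    origin: tuple[float, float],
    nodata: float = -9999,
    fmt: str = "%d",
) -> None:
    """Write a 2-D array as an ESRI-style ASCII grid."""
    values = np.asarray(values)
    nrows, ncols = values.shape
    x0, y_top = origin
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0:.6f}\n"
        f"yllcorner {y_top - nrows * cell_size_m:.6f}\n"
        f"cellsize {cell_size_m:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    with Path(path).open("w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def read_landcover_raster(
    path: str | Path,
    nodata_code: int | None = None,
    year_label: int = 0,
) -> ClassGrid:
    """Read a single-band integer land-cover raster.

    ``.asc``/``.grd``/``.txt`` files are parsed as ASCII grids; anything
    else is handed to :mod:`rasterio` if installed.  Non-integral band
    values raise ``TypeError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".asc", ".grd", ".txt"}:
        values, cellsize, origin, nodata = read_ascii_grid(path)
    else:
        values, cellsize, origin, nodata = _read_geotiff(path)
    if not np.all(np.isfinite(values)) or np.any(values != np.round(values)):
        raise TypeError(f"{path}: land-cover band must contain integer codes")
    code = int(nodata) if nodata_code is None else nodata_code
    return ClassGrid(
        values=values.astype(np.int64),
        cell_size_m=cellsize,
        origin=origin,
        nodata_code=code,
        year_label=year_label,
    )


def _read_geotiff(path: Path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    try:
        import rasterio
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading GeoTIFF requires the optional 'rasterio' dependency; "
            "use the ASCII grid format otherwise"
        ) from exc
    with rasterio.open(path) as src:  # pragma: no cover - optional dependency
        if src.count != 1:
            raise ValueError(f"{path}: expected a single band, found {src.count}")
        transform = src.transform
        if transform.a <= 0 or transform.e >= 0 or abs(transform.a) != abs(transform.e):
            raise ValueError(f"{path}: degenerate or non-square transform {transform}")
        values = src.read(1)
        nodata = src.nodata if src.nodata is not None else -9999
        return values, float(transform.a), (transform.c, transform.f), float(nodata)


def write_class_grid(grid: ClassGrid, path: str | Path) -> None:
    write_ascii_grid(
        grid.values, path, grid.cell_size_m, grid.origin, nodata=grid.nodata_code
    )


def write_habitat_grid(grid: HabitatGrid, path: str | Path) -> None:
    write_ascii_grid(grid.groups, path, grid.cell_size_m, grid.origin, nodata=-9999)


def read_habitat_grid(path: str | Path, year_label: int = 0) -> HabitatGrid:
    values, cellsize, origin, _ = read_ascii_grid(path)
    return HabitatGrid(
        groups=values.astype(np.int8),
        cell_size_m=cellsize,
        origin=origin,
        year_label=year_label,
    )


# ---------------------------------------------------------------------------
# Remapping and the no-hunt covariate
# ---------------------------------------------------------------------------


def remap_to_habitat_groups(grid: ClassGrid, mapping: ClassMapping) -> HabitatGrid:
    """Remap land-cover class codes to habitat groups.

    Cells in ``shelter_food_classes`` become ``SHELTER_FOOD``, cells in
    ``food_classes`` become ``FOOD`` and everything else — including nodata
    and codes absent from the mapping — becomes ``NONE``.
    """
    groups = np.full(grid.shape, HabitatGroup.NONE.value, dtype=np.int8)
    groups[np.isin(grid.values, list(mapping.shelter_food_classes))] = (
        HabitatGroup.SHELTER_FOOD.value
    )
    groups[np.isin(grid.values, list(mapping.food_classes))] = HabitatGroup.FOOD.value
    known = (
        mapping.shelter_food_classes
        | mapping.food_classes
        | mapping.no_hunt_classes
        | set(NLCD_VOCABULARY)
        | {grid.nodata_code}
    )
    unknown = set(np.unique(grid.values).tolist()) - known
    if unknown:
        logger.info("unmapped class codes treated as NONE: %s", sorted(unknown))
    return HabitatGrid(
        groups=groups,
        cell_size_m=grid.cell_size_m,
        origin=grid.origin,
        year_label=grid.year_label,
    )


def no_hunt_area(grid: ClassGrid, mapping: ClassMapping, units) -> pd.DataFrame:
    """Per-unit area (km²) of no-hunt land cover (developed + open water).

    A cell counts toward the unit containing its center.  Returns a frame
    with columns ``unit_id``, ``level``, ``no_hunt_km2``.
    """
    from deerlcu.aggregation import assign_cells_to_units

    if len(units) == 0:
        raise ValueError("empty spatial unit set")
    no_hunt = np.isin(grid.values, list(mapping.no_hunt_classes))
    cell_km2 = (grid.cell_size_m / 1000.0) ** 2
    rows = []
    for level in units.levels():
        membership = assign_cells_to_units(grid, units, level)
        level_units = units.at_level(level)
        for idx, unit in enumerate(level_units):
            n = int(np.count_nonzero(no_hunt & (membership == idx)))
            rows.append(
                {"unit_id": unit.unit_id, "level": level, "no_hunt_km2": n * cell_km2}
            )
    return pd.DataFrame(rows, columns=["unit_id", "level", "no_hunt_km2"])
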