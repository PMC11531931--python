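"""Patch labeling, minimum-area filtering and proximal inclusion.

A patch is a maximal 8-connected component of same-group habitat cells
(diagonal contact counts).  Patches below the minimum area (default
0.02 km², i.e. 23 cells at 30 m resolution) are dropped, but habitat cells
of the same group whose centers lie within a proximity radius (default
500 m, a deer home-range radius) of a surviving patch are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from deerlcu.landcover import HabitatGrid, HabitatGroup

#: 8-connectivity: side or corner contact joins cells into one patch.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PatchLabeling:
    """Connected-component labeling of one habitat group's cells.

    ``labels`` holds 0 for cells outside the group and 1..K for the K
    patches.  ``patch_cells[k - 1]`` is the cell count of patch ``k``.
    """

    labels: np.ndarray
    patch_group: HabitatGroup
    patch_cells: np.ndarray
    cell_size_m: float

    @property
    def n_patches(self) -> int:
        return len(self.patch_cells)

    @property
    def patch_area_m2(self) -> np.ndarray:
        return self.patch_cells * self.cell_size_m**2


@dataclass(frozen=True)
class QualifyingMask:
    """Cells of one group retained as usable habitat.

    ``qualifying_patch_mask`` marks cells of ≥ min-area patches only;
    ``qualifying`` additionally includes proximal disconnected cells.
    """

    qualifying: np.ndarray
    qualifying_patch_mask: np.ndarray
    group: HabitatGroup
    cell_size_m: float

    def __post_init__(self) -> None:
        if self.qualifying.shape != self.qualifying_patch_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.qualifying_patch_mask & ~self.qualifying):
            raise ValueError("qualifying_patch_mask must be a subset of qualifying")


def label_patches(grid: HabitatGrid, group: HabitatGroup) -> PatchLabeling:
    """Label maximal 8-connected patches of ``group`` cells."""
    if group not in (HabitatGroup.SHELTER_FOOD, HabitatGroup.FOOD):
        raise ValueError(f"cannot label patches of group {group!r}")
    mask = grid.mask(group)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return PatchLabeling(
        labels=labels,
        patch_group=group,
        patch_cells=counts,
        cell_size_m=grid.cell_size_m,
    )


def filter_min_area(labeling: PatchLabeling, min_area_km2: float = 0.02) -> set[int]:
    """Labels of patches with area ≥ ``min_area_km2`` (closed threshold)."""
    if min_area_km2 < 0:
        raise ValueError("min_area_km2 must be nonnegative")
    ok = labeling.patch_area_m2 >= min_area_km2 * 1e6
    return set((np.nonzero(ok)[0] + 1).tolist())


def include_proximal(
    grid: HabitatGrid,
    labeling: PatchLabeling,
    qualifying_labels: set[int],
    radius_m: float = 500.0,
) -> QualifyingMask:
    """Build the qualifying mask: ≥ min-area patches plus proximal cells.

    A same-group cell outside any qualifying patch is retained when its
    center lies within ``radius_m`` (closed, Euclidean, center-to-center)
    of any cell of a qualifying patch.
    """
    if radius_m < 0:
        raise ValueError("radius_m must be nonnegative")
    group_mask = grid.mask(labeling.patch_group)
    if qualifying_labels:
        patch_mask = np.isin(labeling.labels, list(qualifying_labels))
    else:
        patch_mask = np.zeros_like(group_mask)
    if patch_mask.any():
        dist = ndimage.distance_transform_edt(
            ~patch_mask, sampling=labeling.cell_size_m
        )
        qualifying = group_mask & (dist <= radius_m)
    else:
        qualifying = np.zeros_like(group_mask)
    return QualifyingMask(
        qualifying=qualifying,
        qualifying_patch_mask=patch_mask,
        group=labeling.patch_group,
        cell_size_m=labeling.cell_size_m,
    )


def qualifying_mask(
    grid: HabitatGrid,
    group: HabitatGroup,
    min_area_km2: float = 0.02,
    radius_m: float = 500.0,
) -> QualifyingMask:
    """label → area filter → proximal inclusion, in one call."""
    labeling = label_patches(grid, group)
    keep = filter_min_area(labeling, min_area_km2)
    return include_proximal(grid, labeling, keep, radius_m)
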