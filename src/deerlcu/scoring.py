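"""Distance-band habitat quality scoring.

Each qualifying habitat cell is scored by its Euclidean center-to-center
distance to the nearest qualifying patch (≥ min-area) of the *opposite*
habitat group.  Shelter/food cells never score below 0.6 — remote forest
cores stay usable habitat — while food cells beyond 500 m of shelter score
0 and contribute nothing downstream.

Band functions (distance d in meters):

=================  =====================================================
shelter/food       d ≤ 500 → 1.0; 500 < d ≤ 700 → 0.8; d > 700 → 0.6
food               d < 200 → 1.0; 200 ≤ d ≤ 275 → 0.8; 275 < d ≤ 350 →
                   0.6; 350 < d ≤ 425 → 0.4; 425 < d ≤ 500 → 0.2;
                   d > 500 → 0.0
=================  =====================================================

The printed band edges leave 1 m gaps (e.g. "< 500" then "501–700");
bands here are closed on the far side so every nonnegative distance maps
to exactly one score.  With 30 m cells the gap interiors are unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

from deerlcu.landcover import HabitatGrid, HabitatGroup
from deerlcu.patches import QualifyingMask

#: The score vocabulary; every ScoreGrid value is one of these.
SCORE_VALUES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class DistanceGrid:
    """Per-cell distance (m) to the nearest qualifying patch cell of
    ``target_group``; infinite where no target exists."""

    dist_m: np.ndarray
    target_group: HabitatGroup
    cell_size_m: float


@dataclass(frozen=True)
class ScoreGrid:
    """Per-cell habitat quality scores in {0, 0.2, 0.4, 0.6, 0.8, 1.0}."""

    scores: np.ndarray
    cell_size_m: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    year_label: int = 0

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if not np.isin(scores, SCORE_VALUES).all():
            bad = np.unique(scores[~np.isin(scores, SCORE_VALUES)])
            raise ValueError(f"scores outside the band vocabulary: {bad.tolist()}")
        object.__setattr__(self, "scores", scores)

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    cell_centers = HabitatGrid.cell_centers


def distance_to_opposite(
    qualifying: QualifyingMask, targets: QualifyingMask
) -> DistanceGrid:
    """Distance from every cell to the nearest qualifying-patch cell of the
    opposite group.

    Only the target's ``qualifying_patch_mask`` attracts — proximally
    included stragglers are scored but are not scoring targets.  Returns
    all-infinite distances when the target group has no qualifying patch.
    """
    if qualifying.qualifying.shape != targets.qualifying_patch_mask.shape:
        raise ValueError(
            f"shape mismatch: {qualifying.qualifying.shape} vs "
            f"{targets.qualifying_patch_mask.shape}"
        )
    target_mask = targets.qualifying_patch_mask
    if target_mask.any():
        dist = ndimage.distance_transform_edt(
            ~target_mask, sampling=qualifying.cell_size_m
        ).astype(float)
    else:
        dist = np.full(target_mask.shape, np.inf)
    return DistanceGrid(
        dist_m=dist, target_group=targets.group, cell_size_m=qualifying.cell_size_m
    )


def score_shelter_food(dist_m):
    """Quality score of a shelter/food cell at distance ``dist_m`` from the
    nearest qualifying food patch (1 / 0.8 / 0.6 floor)."""
    d = np.asarray(dist_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    out = np.select([d <= 500.0, d <= 700.0], [1.0, 0.8], default=0.6)
    return float(out) if np.isscalar(dist_m) else out


def score_food(dist_m):
    """Quality score of a food cell at distance ``dist_m`` from the nearest
    qualifying shelter/food patch (1 down to 0 beyond 500 m)."""
    d = np.asarray(dist_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    out = np.select(
        [d < 200.0, d <= 275.0, d <= 350.0, d <= 425.0, d <= 500.0],
        [1.0, 0.8, 0.6, 0.4, 0.2],
        default=0.0,
    )
    return float(out) if np.isscalar(dist_m) else out


def score_grid(
    habitat: HabitatGrid, masks: Mapping[HabitatGroup, QualifyingMask]
) -> ScoreGrid:
    """Score every qualifying habitat cell; all other cells score 0."""
    sf_mask = masks[HabitatGroup.SHELTER_FOOD]
    food_mask = masks[HabitatGroup.FOOD]
    scores = np.zeros(habitat.shape, dtype=float)

    d_to_food = distance_to_opposite(sf_mask, food_mask).dist_m
    sel = sf_mask.qualifying
    scores[sel] = score_shelter_food(d_to_food[sel])

    d_to_sf = distance_to_opposite(food_mask, sf_mask).dist_m
    sel = food_mask.qualifying
    scores[sel] = score_food(d_to_sf[sel])

    return ScoreGrid(
        scores=scores,
        cell_size_m=habitat.cell_size_m,
        origin=habitat.origin,
        year_label=habitat.year_label,
    )
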