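"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (python loops, all-pairs scans) and
shares no code with the package paths it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_label(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components of a boolean grid via BFS flood fill.

    Returns a list of cell-coordinate sets (order unspecified).
    """
    nrows, ncols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for r in range(nrows):
        for c in range(ncols):
            if not mask[r, c] or seen[r, c]:
                continue
            comp = set()
            queue = deque([(r, c)])
            seen[r, c] = True
            while queue:
                cr, cc = queue.popleft()
                comp.add((cr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = cr + dr, cc + dc
                        if (
                            0 <= nr < nrows
                            and 0 <= nc < ncols
                            and mask[nr, nc]
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            queue.append((nr, nc))
            components.append(comp)
    return components


def brute_force_distance(source_shape: tuple[int, int], targets: np.ndarray, cell_size: float) -> np.ndarray:
    """All-pairs minimum center-to-center distance to any True target cell."""
    out = np.full(source_shape, np.inf)
    target_cells = np.argwhere(targets)
    for r in range(source_shape[0]):
        for c in range(source_shape[1]):
            best = math.inf
            for tr, tc in target_cells:
                d = math.hypot(r - tr, c - tc) * cell_size
                if d < best:
                    best = d
            out[r, c] = best
    return out


def brute_force_distance_fast(
    source_shape: tuple[int, int], targets: np.ndarray, cell_size: float
) -> np.ndarray:
    """Vectorized all-pairs minimum distance (still brute force: computes
    the full cell-by-target distance matrix, no transform tricks)."""
    target_cells = np.argwhere(targets).astype(float)
    if len(target_cells) == 0:
        return np.full(source_shape, np.inf)
    rr, cc = np.meshgrid(
        np.arange(source_shape[0]), np.arange(source_shape[1]), indexing="ij"
    )
    cells = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    from scipy.spatial.distance import cdist

    d = cdist(cells, target_cells).min(axis=1) * cell_size
    return d.reshape(source_shape)


def reference_band_shelter_food(d: float) -> float:
    if d <= 500:
        return 1.0
    if d <= 700:
        return 0.8
    return 0.6


def reference_band_food(d: float) -> float:
    if d < 200:
        return 1.0
    if d <= 275:
        return 0.8
    if d <= 350:
        return 0.6
    if d <= 425:
        return 0.4
    if d <= 500:
        return 0.2
    return 0.0


def reference_score_pipeline(
    groups: np.ndarray,
    cell_size: float = 30.0,
    min_area_km2: float = 0.02,
    radius_m: float = 500.0,
) -> np.ndarray:
    """End-to-end per-cell scores computed entirely by brute force.

    groups: 0 = none, 1 = shelter/food, 2 = food.
    """
    min_cells = min_area_km2 * 1e6 / cell_size**2
    patch_masks = {}
    qualifying = {}
    for group in (1, 2):
        comps = flood_fill_label(groups == group)
        big = [comp for comp in comps if len(comp) >= min_cells]
        pmask = np.zeros(groups.shape, dtype=bool)
        for comp in big:
            for r, c in comp:
                pmask[r, c] = True
        patch_masks[group] = pmask
        dist = brute_force_distance(groups.shape, pmask, cell_size)
        qualifying[group] = (groups == group) & (dist <= radius_m)

    scores = np.zeros(groups.shape)
    for group, other, band in (
        (1, 2, reference_band_shelter_food),
        (2, 1, reference_band_food),
    ):
        dist = brute_force_distance(groups.shape, patch_masks[other], cell_size)
        for r, c in np.argwhere(qualifying[group]):
            scores[r, c] = band(dist[r, c])
    return scores


def point_in_polygon(px: float, py: float, vertices: list[tuple[float, float]]) -> bool:
    """Ray-casting point-in-polygon test (shapely-free)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside
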