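"""Synthetic inputs: clustered landscapes, nested units, density panels.

Everything the scoring pipeline and the regression consume can be generated
here with fixed seeds, so the full workflow is testable offline:

* :func:`generate_landscape` — clustered multi-class land-cover grids via
  rank-thresholded smoothed Gaussian noise (exact class proportions,
  tunable spatial autocorrelation).
* :func:`generate_units` — a rectangular TRS/township/county tiling with
  exact nesting, mimicking PLSS structure (36 sections per township).
* :func:`simulate_density_panel` — a generative twin of the validation
  model: log mu = alpha + X·beta + u[unit] + v[year], y ~ Gamma(shape,
  shape/mu).
* :func:`recovery_report` — truth-vs-posterior coverage table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from deerlcu.aggregation import SpatialUnit, SpatialUnitSet
from deerlcu.landcover import ClassGrid
from deerlcu.validation import COVARIATE_COLS, RESPONSE_COL, RegressionResult

#: NLCD release years used as default panel year labels.
NLCD_YEARS = (2001, 2004, 2006, 2008, 2011, 2013, 2016, 2019, 2021)

#: Default class proportions, loosely Illinois-like: crops dominate, forest
#: and developed land follow.
DEFAULT_PROPORTIONS = {
    82: 0.40,  # cultivated crops
    41: 0.18,  # deciduous forest
    81: 0.10,  # pasture/hay
    71: 0.07,  # grassland
    90: 0.05,  # woody wetlands
    21: 0.08,  # developed, open
    22: 0.05,  # developed, low
    11: 0.04,  # open water
    31: 0.03,  # barren
}


@dataclass(frozen=True)
class LandscapeParams:
    """Recipe for one synthetic land-cover grid."""

    nrows: int = 200
    ncols: int = 200
    cell_size_m: float = 30.0
    proportions: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    clustering: float = 3.0  # Gaussian smoothing sigma, in cells; 0 = iid
    origin: tuple[float, float] = (0.0, 0.0)
    year_label: int = 2021
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid dimensions must be >= 1")
        total = sum(self.proportions.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("class proportions must be nonnegative")
        if self.clustering < 0:
            raise ValueError("clustering must be nonnegative")


def generate_landscape(params: LandscapeParams) -> ClassGrid:
    """Generate a clustered categorical grid with exact class proportions.

    A Gaussian random field is smoothed with sigma = ``clustering`` cells
    and cells are assigned to classes by field-value rank, in the order the
    classes appear in ``proportions``.  Larger clustering produces larger
    same-class patches; clustering 0 degenerates to a random spatial
    shuffle of the target composition.
    """
    rng = np.random.default_rng(params.seed)
    n = params.nrows * params.ncols
    fld = rng.standard_normal((params.nrows, params.ncols))
    if params.clustering > 0:
        fld = ndimage.gaussian_filter(fld, sigma=params.clustering, mode="reflect")

    order = np.argsort(fld.ravel(), kind="stable")
    codes = list(params.proportions)
    counts = np.floor(np.array([params.proportions[c] for c in codes]) * n).astype(int)
    # distribute rounding remainders to the largest classes
    for i in np.argsort(-counts)[: n - counts.sum()]:
        counts[i] += 1
    values = np.empty(n, dtype=np.int64)
    start = 0
    for code, cnt in zip(codes, counts):
        values[order[start : start + cnt]] = code
        start += cnt
    return ClassGrid(
        values=values.reshape(params.nrows, params.ncols),
        cell_size_m=params.cell_size_m,
        origin=params.origin,
        nodata_code=-9999,
        year_label=params.year_label,
    )


def generate_units(
    grid: ClassGrid,
    trs_cells: int = 54,
    township_trs: int = 6,
    county_townships: int = 2,
) -> SpatialUnitSet:
    """Tile the grid into nested TRS / township / county rectangles.

    TRS tiles are ``trs_cells`` × ``trs_cells`` (54 cells at 30 m ≈
    2.6 km², the median section size); townships are ``township_trs``²
    blocks of sections (6×6 = 36, the PLSS layout) and counties are
    ``county_townships``² blocks of townships.  Only full TRS tiles are
    kept; edge townships/counties may hold fewer children.  Units carry
    grid-aligned box geometries, exact areas and parent links.
    """
    nrows, ncols = grid.shape
    n_trs_r, n_trs_c = nrows // trs_cells, ncols // trs_cells
    if n_trs_r < 1 or n_trs_c < 1:
        raise ValueError(
            f"grid {grid.shape} smaller than one {trs_cells}x{trs_cells} TRS tile"
        )
    cell = grid.cell_size_m
    x0, y0 = grid.origin
    tile_km2 = (trs_cells * cell / 1000.0) ** 2

    def tile_box(r0: int, c0: int, r1: int, c1: int):
        # rows grow southward from the top-left origin
        return box(x0 + c0 * cell, y0 - r1 * cell, x0 + c1 * cell, y0 - r0 * cell)

    units: list[SpatialUnit] = []
    for tr in range(n_trs_r):
        for tc in range(n_trs_c):
            twn = (tr // township_trs, tc // township_trs)
            units.append(
                SpatialUnit(
                    unit_id=f"TRS_{tr}_{tc}",
                    level="TRS",
                    area_km2=tile_km2,
                    geometry=tile_box(
                        tr * trs_cells,
                        tc * trs_cells,
                        (tr + 1) * trs_cells,
                        (tc + 1) * trs_cells,
                    ),
                    parent=f"TWN_{twn[0]}_{twn[1]}",
                )
            )

    n_twn_r = -(-n_trs_r // township_trs)
    n_twn_c = -(-n_trs_c // township_trs)
    for wr in range(n_twn_r):
        for wc in range(n_twn_c):
            r0 = wr * township_trs
            c0 = wc * township_trs
            r1 = min((wr + 1) * township_trs, n_trs_r)
            c1 = min((wc + 1) * township_trs, n_trs_c)
            cty = (wr // county_townships, wc // county_townships)
            units.append(
                SpatialUnit(
                    unit_id=f"TWN_{wr}_{wc}",
                    level="TOWNSHIP",
                    area_km2=(r1 - r0) * (c1 - c0) * tile_km2,
                    geometry=tile_box(
                        r0 * trs_cells, c0 * trs_cells, r1 * trs_cells, c1 * trs_cells
                    ),
                    parent=f"CTY_{cty[0]}_{cty[1]}",
                )
            )

    n_cty_r = -(-n_twn_r // county_townships)
    n_cty_c = -(-n_twn_c // county_townships)
    for yr in range(n_cty_r):
        for yc in range(n_cty_c):
            tw_r0 = yr * county_townships * township_trs
            tw_c0 = yc * county_townships * township_trs
            tw_r1 = min((yr + 1) * county_townships * township_trs, n_trs_r)
            tw_c1 = min((yc + 1) * county_townships * township_trs, n_trs_c)
            units.append(
                SpatialUnit(
                    unit_id=f"CTY_{yr}_{yc}",
                    level="COUNTY",
                    area_km2=(tw_r1 - tw_r0) * (tw_c1 - tw_c0) * tile_km2,
                    geometry=tile_box(
                        tw_r0 * trs_cells,
                        tw_c0 * trs_cells,
                        tw_r1 * trs_cells,
                        tw_c1 * trs_cells,
                    ),
                )
            )
    return SpatialUnitSet(units)


@dataclass(frozen=True)
class PanelParams:
    """True parameters of a generative density panel.

    ``beta`` is ordered as the covariate columns (lcu, no_hunt_km2,
    public_hunt_sites, deer_density_prev).  Defaults are the TRS-level
    posterior means so recovery runs exercise the reference regime.

    Covariates are drawn standard normal and the true coefficients apply
    to their 2-SD-standardized version, the same scale the fitting
    routine estimates on — fitted and generating coefficients are then
    directly comparable.  Synthetic covariates are therefore unitless and
    may be negative; they are stand-ins, not physical densities.
    """

    n_units: int = 500
    n_years: int = 9
    level: str = "TRS"
    alpha: float = -0.084
    beta: tuple[float, ...] = (0.344, 0.21, 0.075, 0.724)
    sigma_unit: float = 0.3
    sigma_year: float = 0.3
    shape: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if self.sigma_unit < 0 or self.sigma_year < 0:
            raise ValueError("group SDs must be nonnegative")
        if len(self.beta) != len(COVARIATE_COLS):
            raise ValueError(f"beta must have {len(COVARIATE_COLS)} entries")


def simulate_density_panel(
    units: SpatialUnitSet | int | None,
    params: PanelParams,
    lcu_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate a (unit × year) density panel from the generative model.

    ``units`` may be a :class:`SpatialUnitSet` (its ``params.level`` units
    are used), an integer unit count, or None (``params.n_units``).  When
    an LCU table is supplied its per-unit/per-year ``lcu`` values replace
    the synthetic lcu covariate.  Responses are strictly positive Gamma
    draws with mean exp(alpha + X_scaled·beta + u + v).
    """
    rng = np.random.default_rng(params.seed)
    if isinstance(units, SpatialUnitSet):
        unit_ids = [u.unit_id for u in units.at_level(params.level)]
    else:
        n_units = params.n_units if units is None else int(units)
        unit_ids = [f"{params.level}_{i:04d}" for i in range(n_units)]
    years = list(NLCD_YEARS[: params.n_years])
    if len(years) < params.n_years:
        years += [NLCD_YEARS[-1] + 1 + i for i in range(params.n_years - len(years))]

    idx = pd.MultiIndex.from_product([unit_ids, years], names=["unit_id", "year_label"])
    df = pd.DataFrame(index=idx).reset_index()
    n = len(df)
    X = rng.standard_normal((n, len(COVARIATE_COLS)))
    for j, col in enumerate(COVARIATE_COLS):
        df[col] = X[:, j]
    if lcu_table is not None:
        lookup = lcu_table.set_index(["unit_id", "year"])["lcu"]
        df["lcu"] = [
            lookup.loc[(u, y)] for u, y in zip(df["unit_id"], df["year_label"])
        ]

    # true coefficients act on the 2-SD-standardized covariates
    X_scaled = np.column_stack(
        [
            (df[c] - df[c].mean()) / (2.0 * df[c].std(ddof=1))
            for c in COVARIATE_COLS
        ]
    )
    u = params.sigma_unit * rng.standard_normal(len(unit_ids))
    v = params.sigma_year * rng.standard_normal(len(years))
    unit_codes = pd.factorize(df["unit_id"])[0]
    year_codes = pd.factorize(df["year_label"])[0]
    eta = params.alpha + X_scaled @ np.asarray(params.beta) + u[unit_codes] + v[year_codes]
    mu = np.exp(eta)
    df[RESPONSE_COL] = rng.gamma(shape=params.shape, scale=mu / params.shape)
    # Gamma draws are strictly positive; guard against underflow to 0
    tiny = np.finfo(float).tiny
    df[RESPONSE_COL] = df[RESPONSE_COL].clip(lower=tiny)
    return df


def recovery_report(
    true_params: PanelParams, fitted: RegressionResult
) -> pd.DataFrame:
    """Truth vs posterior for every model parameter, with CrI coverage."""
    truths = {"Intercept": true_params.alpha}
    for name, b in zip(COVARIATE_COLS, true_params.beta):
        truths[name] = b
    truths["sigma_unit"] = true_params.sigma_unit
    truths["sigma_year"] = true_params.sigma_year
    truths["shape"] = true_params.shape

    summary = fitted.summary()
    missing = set(truths) - set(summary.index)
    if missing:
        raise KeyError(f"fitted result lacks parameters: {sorted(missing)}")
    rows = []
    for name, truth in truths.items():
        s = summary.loc[name]
        rows.append(
            {
                "parameter": name,
                "truth": truth,
                "posterior_mean": s["mean"],
                "ci_lower": s["ci_lower"],
                "ci_upper": s["ci_upper"],
                "covered": bool(s["ci_lower"] <= truth <= s["ci_upper"]),
            }
        )
    return pd.DataFrame(rows)
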