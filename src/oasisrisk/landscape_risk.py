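"""Landscape pattern indices and the ecological risk index (ERI).

The risk model follows the landscape-ecology convention for arid-zone
cities.  For each landscape type *i* over a study area of total area *A*:

- fragmentation  ``C_i = N_i / A_i``  (patches per km^2),
- separation     ``S_i = (A / (2 A_i)) * sqrt(N_i / A)``,
- dominance      ``D_i = (Q_i + M_i) / 4 + L_i / 2`` with
  *Q_i* the fraction of sampling cells where the type occurs, *M_i* its
  share of all patches, and *L_i* its share of total area,
- disturbance    ``LDI_i = a C_i + b S_i + c D_i`` with weights
  (0.5, 0.3, 0.2) for utilized land and (0.3, 0.2, 0.5) for unutilized,
- fragility      ``LFI_i`` = the type's vulnerability rank, sum-normalized
  over all types.

On a square sampling grid (1 km cells by default) the per-cell risk is the
composition-weighted disturbance-fragility product

    ``ERI_k = sum_i (A_ki / A_k) * LDI_i * LFI_i``

which is a convex combination, hence bounded by ``max_i LDI_i * LFI_i``.
Indices are computed globally per type per epoch; the per-cell variation
of ERI comes entirely through the composition ``A_ki``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .raster import Raster

__all__ = [
    "LAND_CLASSES",
    "DEFAULT_STATUS",
    "DEFAULT_FRAGILITY_RANKS",
    "UTILIZED_WEIGHTS",
    "UNUTILIZED_WEIGHTS",
    "PatchStats",
    "LandscapeIndices",
    "RiskGrid",
    "patch_stats",
    "fragmentation",
    "separation",
    "dominance",
    "disturbance",
    "fragility",
    "landscape_indices",
    "build_risk_grid",
    "eri",
    "classify_risk_levels",
    "idw_surface",
]

#: Seven-class land-use scheme (codes are raster values).
LAND_CLASSES = {
    1: "cropland",
    2: "forestland",
    3: "grassland_high",
    4: "grassland_lowmed",
    5: "water",
    6: "builtup",
    7: "unused",
}

#: Utilized/unutilized split: only unused land counts as unutilized.
DEFAULT_STATUS = {
    "cropland": "utilized",
    "forestland": "utilized",
    "grassland_high": "utilized",
    "grassland_lowmed": "utilized",
    "water": "utilized",
    "builtup": "utilized",
    "unused": "unutilized",
}

#: Vulnerability ranks, high to low: construction 6, forest 5, arable 4,
#: grassland 3 (both coverage classes share the rank), water 2, desert 1.
DEFAULT_FRAGILITY_RANKS = {
    "builtup": 6,
    "forestland": 5,
    "cropland": 4,
    "grassland_high": 3,
    "grassland_lowmed": 3,
    "water": 2,
    "unused": 1,
}

UTILIZED_WEIGHTS = (0.5, 0.3, 0.2)
UNUTILIZED_WEIGHTS = (0.3, 0.2, 0.5)


@dataclass
class PatchStats:
    """Per-type patch counts and areas over the mapped study area.

    ``table`` is indexed by class name with columns ``Ni`` (patch count)
    and ``Ai`` (km^2); ``total_area_km2`` is the non-nodata area *A*.
    """

    table: pd.DataFrame
    total_area_km2: float

    def __post_init__(self) -> None:
        if self.table["Ai"].sum() > self.total_area_km2 + 1e-9:
            raise ValueError("sum of class areas exceeds total area")


@dataclass
class LandscapeIndices:
    """Global per-type indices: Ni, Ai, Ci, Si, Di, LDI, LFI, status."""

    table: pd.DataFrame


@dataclass
class RiskGrid:
    """Square sampling cells with per-type composition and per-cell ERI.

    ``cells`` has one row per retained cell: grid indices ``grow``/``gcol``,
    in-study area ``area_km2``, one composition column per class name
    (km^2), and — once computed — ``eri`` and ordinal ``level``.
    """

    cells: pd.DataFrame
    grid_size_m: float
    class_names: list[str]
    breaks: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def composition(self) -> pd.DataFrame:
        return self.cells[self.class_names]


def patch_stats(landuse: Raster, connectivity: int = 8) -> PatchStats:
    """Count connected patches and areas per landscape type.

    ``connectivity`` 4 joins edge-sharing cells only; 8 also joins
    diagonal neighbours (the remote-sensing default here).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    valid = landuse.mask()
    if not valid.any():
        raise ValueError("land-use raster has no valid cells")
    conn = 1 if connectivity == 4 else 2
    cell_area = landuse.cell_area_km2
    codes = np.unique(landuse.data[valid])
    rows = {}
    for code in codes:
        m = (landuse.data == code) & valid
        n_patches = int(measure.label(m, connectivity=conn).max())
        rows[LAND_CLASSES.get(int(code), str(int(code)))] = {
            "Ni": n_patches,
            "Ai": float(m.sum()) * cell_area,
        }
    table = pd.DataFrame(rows).T
    table["Ni"] = table["Ni"].astype(int)
    return PatchStats(table, total_area_km2=float(valid.sum()) * cell_area)


def fragmentation(stats: PatchStats, name: str) -> float:
    """C_i = N_i / A_i, patches per km^2."""
    ni, ai = stats.table.loc[name, ["Ni", "Ai"]]
    if ai <= 0:
        raise ValueError(f"type {name!r} has zero area")
    return float(ni) / float(ai)


def separation(stats: PatchStats, name: str) -> float:
    """S_i = (A / (2 A_i)) * sqrt(N_i / A)."""
    ni, ai = stats.table.loc[name, ["Ni", "Ai"]]
    a = stats.total_area_km2
    if ai <= 0 or a <= 0:
        raise ValueError(f"type {name!r} has zero area")
    return a / (2.0 * float(ai)) * float(np.sqrt(float(ni) / a))


def dominance(grid: RiskGrid, stats: PatchStats, name: str) -> float:
    """D_i = (Q_i + M_i) / 4 + L_i / 2, in [0, 1]."""
    if len(grid.cells) == 0:
        raise ValueError("risk grid is empty")
    if name not in stats.table.index or stats.table.loc[name, "Ai"] == 0:
        return 0.0
    qi = float((grid.cells[name] > 0).mean()) if name in grid.cells else 0.0
    mi = float(stats.table.loc[name, "Ni"]) / float(stats.table["Ni"].sum())
    li = float(stats.table.loc[name, "Ai"]) / stats.total_area_km2
    return (qi + mi) / 4.0 + li / 2.0


def disturbance(ci: float, si: float, di: float, land_status: str) -> float:
    """LDI = a*Ci + b*Si + c*Di with status-dependent weights."""
    if land_status == "utilized":
        a, b, c = UTILIZED_WEIGHTS
    elif land_status == "unutilized":
        a, b, c = UNUTILIZED_WEIGHTS
    else:
        raise ValueError(f"unknown land status {land_status!r}")
    return a * ci + b * si + c * di


def fragility(ranks: dict[str, float] | None = None) -> dict[str, float]:
    """Sum-normalized vulnerability ranks; values sum to 1."""
    ranks = DEFAULT_FRAGILITY_RANKS if ranks is None else ranks
    if any(r <= 0 for r in ranks.values()):
        raise ValueError("fragility ranks must be positive")
    total = float(sum(ranks.values()))
    return {k: v / total for k, v in ranks.items()}


def landscape_indices(
    landuse: Raster,
    grid: RiskGrid,
    connectivity: int = 8,
    status: dict[str, str] | None = None,
    ranks: dict[str, float] | None = None,
) -> LandscapeIndices:
    """Compute the full per-type index table for one epoch."""
    status = DEFAULT_STATUS if status is None else status
    stats = patch_stats(landuse, connectivity=connectivity)
    lfi = fragility(ranks)
    rows = {}
    for name in stats.table.index:
        st = status.get(name)
        if st is None:
            raise ValueError(f"no utilized/unutilized status for type {name!r}")
        if name not in lfi:
            raise ValueError(f"no fragility rank for type {name!r}")
        ci = fragmentation(stats, name)
        si = separation(stats, name)
        di = dominance(grid, stats, name)
        rows[name] = {
            "Ni": stats.table.loc[name, "Ni"],
            "Ai": stats.table.loc[name, "Ai"],
            "Ci": ci,
            "Si": si,
            "Di": di,
            "LDI": disturbance(ci, si, di, st),
            "LFI": lfi[name],
            "status": st,
        }
    return LandscapeIndices(pd.DataFrame(rows).T)


def build_risk_grid(
    landuse: Raster,
    grid_size_m: float = 1000.0,
    coverage_floor: float = 0.1,
) -> RiskGrid:
    """Tile the raster into square sampling cells and tabulate composition.

    Cells whose in-study coverage is below ``coverage_floor`` of the full
    cell area are dropped so boundary slivers do not produce unstable
    compositions.
    """
    if grid_size_m <= 0:
        raise ValueError("grid_size_m must be positive")
    block = max(1, int(round(grid_size_m / landuse.cell_size)))
    nrows, ncols = landuse.shape
    valid = landuse.mask()
    cell_area = landuse.cell_area_km2
    full_cell = (block * landuse.cell_size / 1000.0) ** 2
    names_present = [
        LAND_CLASSES.get(int(c), str(int(c))) for c in np.unique(landuse.data[valid])
    ]
    records = []
    for gr in range(int(np.ceil(nrows / block))):
        for gc in range(int(np.ceil(ncols / block))):
            sl = (
                slice(gr * block, min((gr + 1) * block, nrows)),
                slice(gc * block, min((gc + 1) * block, ncols)),
            )
            v = valid[sl]
            if not v.any():
                continue
            a_k = float(v.sum()) * cell_area
            if a_k < coverage_floor * full_cell:
                continue
            rec = {"grow": gr, "gcol": gc, "area_km2": a_k}
            vals = landuse.data[sl][v]
            for code, cnt in zip(*np.unique(vals, return_counts=True)):
                rec[LAND_CLASSES.get(int(code), str(int(code)))] = cnt * cell_area
            records.append(rec)
    cells = pd.DataFrame(records)
    for name in names_present:
        if name not in cells:
            cells[name] = 0.0
    cells[names_present] = cells[names_present].fillna(0.0)
    return RiskGrid(cells, grid_size_m=grid_size_m, class_names=names_present)


def eri(grid: RiskGrid, indices: LandscapeIndices) -> RiskGrid:
    """Attach per-cell ERI_k = sum_i (A_ki / A_k) * LDI_i * LFI_i."""
    risk = indices.table["LDI"].astype(float) * indices.table["LFI"].astype(float)
    vals = np.zeros(len(grid.cells))
    for name, r in risk.items():
        if name in grid.cells:
            vals += grid.cells[name].to_numpy(dtype=float) * float(r)
    grid.cells = grid.cells.copy()
    grid.cells["eri"] = vals / grid.cells["area_km2"].to_numpy(dtype=float)
    return grid


def classify_risk_levels(
    grids: list[RiskGrid] | RiskGrid, n_levels: int = 5
) -> np.ndarray:
    """Equal-interval risk levels over the pooled ERI range of all epochs.

    One shared break set is used for every supplied grid so levels are
    comparable across epochs; breaks are stored on each grid (``breaks``)
    and levels written to the ``level`` column.  A constant ERI field
    yields a single level with a warning.
    """
    if isinstance(grids, RiskGrid):
        grids = [grids]
    pooled = np.concatenate([g.cells["eri"].to_numpy(dtype=float) for g in grids])
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        warnings.warn("constant ERI field; assigning a single risk level", stacklevel=2)
        breaks = np.array([lo, lo])
        for g in grids:
            g.cells["level"] = 1
            g.breaks = breaks
        return breaks
    breaks = np.linspace(lo, hi, n_levels + 1)
    for g in grids:
        lev = np.digitize(g.cells["eri"].to_numpy(dtype=float), breaks[1:-1]) + 1
        g.cells["level"] = lev
        g.breaks = breaks
    return breaks


def idw_surface(
    grid: RiskGrid, shape: tuple[int, int], power: float = 2.0
) -> np.ndarray:
    """Inverse-distance-weighted ERI surface for map display only.

    Analysis always uses the raw cell values; this exists so maps can be
    drawn from the coarse sampling grid.
    """
    pts = grid.cells[["grow", "gcol"]].to_numpy(dtype=float)
    vals = grid.cells["eri"].to_numpy(dtype=float)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    scale_r = shape[0] / (pts[:, 0].max() + 1.0)
    scale_c = shape[1] / (pts[:, 1].max() + 1.0)
    centres = np.stack(
        [(pts[:, 0] + 0.5) * scale_r, (pts[:, 1] + 0.5) * scale_c], axis=1
    )
    d2 = (
        (rr[..., None] - centres[:, 0]) ** 2
        + (cc[..., None] - centres[:, 1]) ** 2
    )
    d2 = np.maximum(d2, 1e-12)
    w = d2 ** (-power / 2.0)
    return (w * vals).sum(axis=-1) / w.sum(axis=-1)
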