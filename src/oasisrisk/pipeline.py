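"""End-to-end pipeline: zonation -> risk -> Moran -> transitions -> scenarios -> drivers.

`run_pipeline` executes every analysis stage for a list of epochs and
writes a machine-readable summary.  All numeric results in the summary
are produced by the module operations; this layer only sequences them
and records the settings used (thresholds, weights, ranks, multipliers,
seeds) so a run is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landscape_risk as lr
from . import spatial, transitions, zonation
from .drivers import DEFAULT_GRID, fit_and_validate, normalize_and_split
from .raster import Raster, read_raster
from .synthetic import SyntheticConfig, generate_driver_table

logger = logging.getLogger("oasisrisk")

__all__ = ["PipelineConfig", "run_pipeline", "risk_grid_to_geojson"]


@dataclass
class PipelineConfig:
    """Inputs and settings of a full multi-epoch run."""

    epochs: list[tuple[int, str, str]]  # (year, ndvi path, landuse path)
    thresholds: zonation.ZoneThresholds = field(
        default_factory=zonation.ZoneThresholds
    )
    grid_size_m: float = 1000.0
    connectivity: int = 8
    weights_scheme: str = "queen"
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    driver_table: str | None = None
    outdir: str = "oasisrisk_out"

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("pipeline needs at least one epoch")
        if self.grid_size_m <= 0:
            raise ValueError("grid_size_m must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        epochs = [
            (int(e["year"]), e["ndvi"], e["landuse"]) for e in raw.pop("epochs")
        ]
        thr = raw.pop("thresholds", None)
        kwargs = dict(raw)
        if thr:
            kwargs["thresholds"] = zonation.ZoneThresholds(
                oasis_min=float(thr.get("oasis_min", 0.30)),
                desert_max=float(thr.get("desert_max", 0.10)),
            )
        return cls(epochs=epochs, **kwargs)


def risk_grid_to_geojson(grid: lr.RiskGrid) -> dict:
    """Risk-grid cells as a GeoJSON FeatureCollection of square polygons."""
    from shapely.geometry import box, mapping

    size = grid.grid_size_m
    features = []
    for _, row in grid.cells.iterrows():
        x0 = row["gcol"] * size
        y1 = -row["grow"] * size  # y decreases with grid row (origin top-left)
        geom = box(x0, y1 - size, x0 + size, y1)
        props = {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in row.items()
        }
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    return {"type": "FeatureCollection", "features": features}


def _epoch_rasters(cfg: PipelineConfig):
    for year, ndvi_path, lu_path in cfg.epochs:
        for p in (ndvi_path, lu_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"epoch {year}: missing input {p}")
        yield year, read_raster(ndvi_path), read_raster(lu_path)


def _grid_cell_zone(zones: Raster, grid: lr.RiskGrid) -> np.ndarray:
    """Majority zone of each risk-grid cell (for per-zone ERI summaries)."""
    block = max(1, int(round(grid.grid_size_m / zones.cell_size)))
    out = np.zeros(len(grid.cells), dtype=np.int64)
    for i, (gr, gc) in enumerate(zip(grid.cells["grow"], grid.cells["gcol"])):
        sl = zones.data[
            gr * block : (gr + 1) * block, gc * block : (gc + 1) * block
        ]
        vals = sl[np.isin(sl, list(zonation.ZONE_LABELS))]
        if vals.size:
            codes, counts = np.unique(vals, return_counts=True)
            out[i] = codes[np.argmax(counts)]
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage for all epochs; return and write the summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "settings: thresholds=(%.2f, %.2f) grid=%sm connectivity=%s "
        "weights=%s/row-standardized permutations=%d alpha=%.2f seed=%d",
        cfg.thresholds.oasis_min, cfg.thresholds.desert_max, cfg.grid_size_m,
        cfg.connectivity, cfg.weights_scheme, cfg.n_permutations, cfg.alpha,
        cfg.seed,
    )
    summary: dict = {
        "settings": {
            "oasis_min": cfg.thresholds.oasis_min,
            "desert_max": cfg.thresholds.desert_max,
            "grid_size_m": cfg.grid_size_m,
            "connectivity": cfg.connectivity,
            "weights_scheme": cfg.weights_scheme,
            "ldi_weights_utilized": list(lr.UTILIZED_WEIGHTS),
            "ldi_weights_unutilized": list(lr.UNUTILIZED_WEIGHTS),
            "fragility_ranks": dict(lr.DEFAULT_FRAGILITY_RANKS),
            "scenario_multipliers": [0.8, 1.3, 1.1],
            "n_permutations": cfg.n_permutations,
            "alpha": cfg.alpha,
            "seed": cfg.seed,
        },
        "epochs": {},
    }
    landuse_by_year: dict[int, Raster] = {}
    grids: list[lr.RiskGrid] = []
    years: list[int] = []
    zones_by_year: dict[int, Raster] = {}

    for year, ndvi, landuse in _epoch_rasters(cfg):
        try:
            zones = zonation.classify_zones(ndvi, cfg.thresholds)
            grid = lr.build_risk_grid(landuse, grid_size_m=cfg.grid_size_m)
            indices = lr.landscape_indices(
                landuse, grid, connectivity=cfg.connectivity
            )
            grid = lr.eri(grid, indices)
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"epoch {year}: risk stage failed: {exc}") from exc
        epoch_summary = {
            "zone_areas_km2": zonation.zone_areas(zones).round(6).to_dict(),
            "eri": {
                "min": float(grid.cells["eri"].min()),
                "max": float(grid.cells["eri"].max()),
                "mean": float(grid.cells["eri"].mean()),
            },
            "indices": {
                name: {
                    k: float(indices.table.loc[name, k])
                    for k in ("Ci", "Si", "Di", "LDI", "LFI")
                }
                for name in indices.table.index
            },
        }
        zone_of_cell = _grid_cell_zone(zones, grid)
        by_zone = {}
        for code, zname in zonation.ZONE_LABELS.items():
            m = zone_of_cell == code
            if m.any():
                by_zone[zname] = float(grid.cells["eri"].to_numpy()[m].mean())
        epoch_summary["eri_mean_by_zone"] = by_zone
        if len(grid.cells) >= 2 and grid.cells["eri"].nunique() > 1:
            w = spatial.build_weights(grid, scheme=cfg.weights_scheme)
            res = spatial.local_moran(
                grid.cells["eri"].to_numpy(),
                w,
                n_permutations=cfg.n_permutations,
                alpha=cfg.alpha,
                seed=cfg.seed,
            )
            counts = pd.Series(res.cluster).value_counts().to_dict()
            epoch_summary["moran"] = {
                "I_global": res.I_global,
                "expected": res.expected,
                "cluster_counts": {k: int(v) for k, v in counts.items()},
            }
        summary["epochs"][str(year)] = epoch_summary
        landuse_by_year[year] = landuse
        zones_by_year[year] = zones
        grids.append(grid)
        years.append(year)

    breaks = lr.classify_risk_levels(grids)
    summary["risk_level_breaks"] = [float(b) for b in breaks]
    for year, grid in zip(years, grids):
        counts = grid.cells["level"].value_counts().sort_index()
        summary["epochs"][str(year)]["risk_level_share_pct"] = {
            str(int(k)): float(100.0 * v / len(grid.cells))
            for k, v in counts.items()
        }
        with open(outdir / f"risk_grid_{year}.geojson", "w") as fh:
            json.dump(risk_grid_to_geojson(grid), fh)
        grid.cells.to_csv(outdir / f"risk_grid_{year}.csv", index=False)

    summary["transitions"] = {}
    markov = None
    if len(years) >= 2:
        for y0, y1 in zip(years[:-1], years[1:]):
            tm = transitions.cross_tabulate(
                landuse_by_year[y0], landuse_by_year[y1],
                labels=lr.LAND_CLASSES, interval=(y0, y1),
            )
            summary["transitions"][f"{y0}-{y1}"] = {
                str(r): {str(c): float(tm.flows.loc[r, c]) for c in tm.flows}
                for r in tm.flows.index
            }
            tm.flows.to_csv(outdir / f"transitions_{y0}_{y1}.csv")
        markov = transitions.estimate_markov(tm)
        areas_now = tm.areas_t1()
        natural = transitions.project_areas(areas_now, markov, n_steps=1)
        gov_P = transitions.apply_scenario(markov, transitions.GOVERNMENT_SCENARIO)
        government = transitions.project_areas(areas_now, gov_P, n_steps=1)
        horizon = years[-1] + (markov.step_years or 10)
        summary["projection"] = {
            "horizon_year": horizon,
            "natural_km2": {str(k): float(v) for k, v in natural.items()},
            "government_km2": {str(k): float(v) for k, v in government.items()},
        }
        markov.P.to_csv(outdir / "markov.csv")

    # driver analysis on the last epoch's sampling cells
    if cfg.driver_table:
        table = pd.read_csv(cfg.driver_table)
    else:
        n = max(len(grids[-1].cells), 50)
        logger.info("no driver table supplied; generating synthetic drivers (n=%d)", n)
        table = generate_driver_table(SyntheticConfig(seed=cfg.seed), n)
        summary["drivers_source"] = "synthetic"
    table = normalize_and_split(table, seed=cfg.seed)
    small_grid = {k: v[:2] for k, v in DEFAULT_GRID.items()}
    report = fit_and_validate(table, grid=small_grid, seed=cfg.seed)
    summary["drivers"] = report.to_dict()

    composition = transitions.zone_composition(
        zones_by_year[years[-1]], landuse_by_year[years[-1]]
    )
    summary["zone_composition_pct"] = {
        str(r): {str(c): float(composition.loc[r, c]) for c in composition}
        for r in composition.index
    }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
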