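"""Land-use change accounting and Markov scenario projection.

Cross-tabulating two co-registered categorical maps gives the transfer
matrix of area flows between classes over the interval; row-normalizing
it yields the Markov transition matrix used to project class areas one
interval at a time (``areas_{t+1} = areas_t @ P``), which conserves total
area exactly.

Policy scenarios are expressed as multiplicative adjustments to targeted
transition probabilities.  The government-regulation scenario bundled
here encodes three rules: a 20 % cut in flows from cropland, woodland and
grassland to built-up and unused land; a 30 % boost of unused land
converting to cropland, woodland and grassland; and a 10 % boost of
built-up land converting to woodland and grassland.  After adjustment
each row's diagonal (persistence) entry absorbs the difference so rows
remain stochastic; if that would drive persistence negative the whole
row is rescaled proportionally instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster

__all__ = [
    "TransitionMatrix",
    "MarkovMatrix",
    "ScenarioSpec",
    "GOVERNMENT_SCENARIO",
    "cross_tabulate",
    "percent_change",
    "estimate_markov",
    "apply_scenario",
    "project_areas",
    "zone_composition",
]


@dataclass
class TransitionMatrix:
    """Area flows (km^2) between classes: rows = class at t0, cols = t1."""

    flows: pd.DataFrame
    interval: tuple[int, int] | None = None

    @property
    def labels(self) -> list:
        return list(self.flows.index)

    def areas_t0(self) -> pd.Series:
        return self.flows.sum(axis=1)

    def areas_t1(self) -> pd.Series:
        return self.flows.sum(axis=0)


@dataclass
class MarkovMatrix:
    """Row-stochastic transition probabilities over one time step."""

    P: pd.DataFrame
    step_years: int | None = None

    def __post_init__(self) -> None:
        arr = self.P.to_numpy(dtype=float)
        if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1 within 1e-9")

    @property
    def labels(self) -> list:
        return list(self.P.index)


@dataclass
class ScenarioSpec:
    """Multiplicative adjustments: (from-classes, to-classes, multiplier)."""

    adjustments: list[tuple[tuple[str, ...], tuple[str, ...], float]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        for _, _, mult in self.adjustments:
            if mult <= 0:
                raise ValueError("scenario multipliers must be positive")


_VEGETATED = ("cropland", "forestland", "grassland_high", "grassland_lowmed")

#: The bundled government-regulation scenario (x0.8, x1.3, x1.1 rules).
GOVERNMENT_SCENARIO = ScenarioSpec(
    [
        (_VEGETATED, ("builtup", "unused"), 0.8),
        (("unused",), _VEGETATED, 1.3),
        (("builtup",), ("forestland", "grassland_high", "grassland_lowmed"), 1.1),
    ]
)


def cross_tabulate(
    map_t0: Raster,
    map_t1: Raster,
    labels: dict[int, str] | None = None,
    interval: tuple[int, int] | None = None,
) -> TransitionMatrix:
    """Area flows between classes of two co-registered categorical maps.

    Cells that are nodata in either epoch are excluded from the common
    mapped area.
    """
    if map_t0.shape != map_t1.shape:
        raise ValueError(
            f"rasters are not co-registered: {map_t0.shape} vs {map_t1.shape}"
        )
    valid = map_t0.mask() & map_t1.mask()
    a = map_t0.data[valid].astype(np.int64)
    b = map_t1.data[valid].astype(np.int64)
    codes = np.unique(np.concatenate([a, b]))
    code_ix = {c: i for i, c in enumerate(codes)}
    k = len(codes)
    joint = np.bincount(
        np.vectorize(code_ix.get)(a) * k + np.vectorize(code_ix.get)(b),
        minlength=k * k,
    ).reshape(k, k)
    if labels is None:
        labels = map_t0.labels or {}
    names = [labels.get(int(c), int(c)) for c in codes]
    flows = pd.DataFrame(
        joint * map_t0.cell_area_km2, index=names, columns=names
    )
    return TransitionMatrix(flows, interval=interval)


def percent_change(area_t0: float, area_t1: float) -> float:
    """Signed percent change 100 * (a1 - a0) / a0."""
    if area_t0 <= 0:
        raise ValueError("percent change is undefined for a zero initial area")
    return 100.0 * (area_t1 - area_t0) / area_t0


def estimate_markov(
    tm: TransitionMatrix, step_years: int | None = None
) -> MarkovMatrix:
    """Row-normalize area flows into transition probabilities.

    A class with no area at t0 cannot be sourced; its row is replaced by
    the identity (full persistence) with a warning.
    """
    flows = tm.flows.to_numpy(dtype=float)
    rowsum = flows.sum(axis=1)
    P = np.zeros_like(flows)
    for i, s in enumerate(rowsum):
        if s > 0:
            P[i] = flows[i] / s
        else:
            warnings.warn(
                f"class {tm.labels[i]!r} absent at t0; identity row substituted",
                stacklevel=2,
            )
            P[i, i] = 1.0
    if step_years is None and tm.interval is not None:
        step_years = tm.interval[1] - tm.interval[0]
    return MarkovMatrix(
        pd.DataFrame(P, index=tm.labels, columns=tm.labels), step_years=step_years
    )


def apply_scenario(markov: MarkovMatrix, spec: ScenarioSpec) -> MarkovMatrix:
    """Scale targeted transition probabilities and restore stochasticity.

    Each matching off-diagonal entry is multiplied by its rule's factor
    (clipped at 1 with a warning if it would exceed 1); the row's diagonal
    then absorbs the net change.  If the diagonal would go negative the
    whole row is rescaled proportionally instead, with a warning.
    """
    P = markov.P.to_numpy(dtype=float).copy()
    labels = markov.labels
    ix = {lab: i for i, lab in enumerate(labels)}
    for from_set, to_set, mult in spec.adjustments:
        for f in from_set:
            if f not in ix:
                continue
            for t in to_set:
                if t not in ix or f == t:
                    continue
                new = P[ix[f], ix[t]] * mult
                if new > 1.0:
                    warnings.warn(
                        f"adjusted P[{f},{t}] exceeds 1; clipped", stacklevel=2
                    )
                    new = 1.0
                P[ix[f], ix[t]] = new
    for i in range(len(labels)):
        off = P[i].sum() - P[i, i]
        if off <= 1.0:
            P[i, i] = 1.0 - off
        else:
            warnings.warn(
                f"row {labels[i]!r}: persistence would go negative; "
                "row rescaled proportionally",
                stacklevel=2,
            )
            P[i] = P[i] / P[i].sum()
    return MarkovMatrix(
        pd.DataFrame(P, index=labels, columns=labels), step_years=markov.step_years
    )


def project_areas(
    areas: pd.Series | np.ndarray, markov: MarkovMatrix, n_steps: int = 1
) -> pd.Series:
    """Iterate areas_{t+1} = areas_t @ P; total area is conserved."""
    if isinstance(areas, pd.Series):
        vec = areas.reindex(markov.labels).to_numpy(dtype=float)
    else:
        vec = np.asarray(areas, dtype=float)
    if vec.shape != (len(markov.labels),):
        raise ValueError("area vector length does not match matrix classes")
    if (vec < 0).any():
        raise ValueError("areas must be non-negative")
    P = markov.P.to_numpy(dtype=float)
    for _ in range(n_steps):
        vec = vec @ P
    return pd.Series(vec, index=markov.labels)


def zone_composition(zones: Raster, landuse: Raster) -> pd.DataFrame:
    """Percent of each land-use class falling in each zone.

    Rows are land-use classes and sum to 100 %; columns are zones.
    """
    if zones.shape != landuse.shape:
        raise ValueError(
            f"rasters are not co-registered: {zones.shape} vs {landuse.shape}"
        )
    valid = zones.mask() & landuse.mask()
    lu = landuse.data[valid].astype(np.int64)
    zn = zones.data[valid].astype(np.int64)
    lu_codes = np.unique(lu)
    zn_codes = np.unique(zn)
    lu_ix = {c: i for i, c in enumerate(lu_codes)}
    zn_ix = {c: i for i, c in enumerate(zn_codes)}
    counts = np.zeros((len(lu_codes), len(zn_codes)))
    flat = np.vectorize(lu_ix.get)(lu) * len(zn_codes) + np.vectorize(zn_ix.get)(zn)
    counts.flat[: len(lu_codes) * len(zn_codes)] = np.bincount(
        flat, minlength=len(lu_codes) * len(zn_codes)
    )
    from .landscape_risk import LAND_CLASSES
    from .zonation import ZONE_LABELS

    table = pd.DataFrame(
        counts,
        index=[LAND_CLASSES.get(int(c), int(c)) for c in lu_codes],
        columns=[ZONE_LABELS.get(int(c), int(c)) for c in zn_codes],
    )
    return table.div(table.sum(axis=1), axis=0) * 100.0
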