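"""Synthetic oasis-desert landscapes with known generating parameters.

Real arid-zone settlements show a concentric structure: a vegetated oasis
core, a sparsely vegetated transition belt, and surrounding desert.  The
generators here emulate that structure — a radially decaying NDVI field, a
patchy categorical land-use map evolved by a known per-cell Markov chain,
and driver surfaces with planted effect sizes on the ecological risk
response — so that every downstream stage of the analysis can be exercised
against ground truth.

All generators are deterministic given ``SyntheticConfig.seed``; each
top-level call derives its own independent sub-stream, so regenerating one
product never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster

__all__ = [
    "SyntheticConfig",
    "DRIVER_NAMES",
    "generate_ndvi",
    "generate_landuse_series",
    "generate_drivers",
    "generate_driver_table",
]

#: The nine candidate drivers of ecological risk: terrain, climate,
#: land degradation, and socioeconomic pressure.
DRIVER_NAMES = (
    "elevation",
    "slope",
    "soil_erosion",
    "temperature",
    "precipitation",
    "gdp",
    "population",
    "distance_to_roads",
    "distance_to_towns",
)

# Plausible marginal scales for each driver surface (location, spread);
# values are arbitrary but dimensionally sensible for an arid-zone city.
_DRIVER_SCALES = {
    "elevation": (900.0, 120.0),        # m
    "slope": (3.0, 2.0),                # degrees
    "soil_erosion": (1500.0, 600.0),    # t km^-2 yr^-1
    "temperature": (11.0, 1.0),         # deg C annual mean
    "precipitation": (150.0, 40.0),     # mm yr^-1
    "gdp": (5000.0, 3000.0),            # CNY 1e4 per km^2
    "population": (200.0, 120.0),       # persons per km^2
    "distance_to_roads": (2000.0, 1500.0),   # m
    "distance_to_towns": (8000.0, 5000.0),   # m
}


class ConfigurationError(ValueError):
    """Raised when a synthetic-landscape configuration is inconsistent."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study area.

    The defaults describe a 200 x 200-cell scene at 30 m resolution with a
    centred oasis whose NDVI decays exponentially with distance, seven
    land-use classes evolving over four decadal epochs, and one dominant
    plus one secondary planted driver of ecological risk.
    """

    grid_shape: tuple[int, int] = (200, 200)
    cell_size: float = 30.0
    seed: int = 0
    oasis_center: tuple[int, int] | None = None
    center_value: float = 0.6
    radial_decay: float = 0.02
    noise_sd: float = 0.02
    n_classes: int = 7
    markov_P: np.ndarray | None = None
    n_epochs: int = 4
    driver_effects: dict[str, float] = field(
        default_factory=lambda: {"distance_to_towns": 1.0, "population": 0.5}
    )
    driver_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ConfigurationError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.radial_decay <= 0:
            raise ConfigurationError("radial_decay must be > 0")
        if self.noise_sd < 0 or self.driver_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if self.n_epochs < 2:
            raise ConfigurationError("n_epochs must be >= 2")
        if self.oasis_center is None:
            self.oasis_center = (rows // 2, cols // 2)
        if self.markov_P is None:
            self.markov_P = _default_markov(self.n_classes)
        self.markov_P = np.asarray(self.markov_P, dtype=float)
        if self.markov_P.shape != (self.n_classes, self.n_classes):
            raise ConfigurationError(
                f"markov_P shape {self.markov_P.shape} does not match "
                f"n_classes={self.n_classes}"
            )
        if (self.markov_P < 0).any():
            raise ConfigurationError("markov_P entries must be non-negative")
        if not np.allclose(self.markov_P.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("markov_P rows must sum to 1 within 1e-9")
        unknown = set(self.driver_effects) - set(DRIVER_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown driver names: {sorted(unknown)}")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible sub-stream for one generator."""
        return np.random.default_rng([int(self.seed), int(stream)])


def _default_markov(k: int) -> np.ndarray:
    """Sticky chain: 0.85 persistence, remainder spread evenly."""
    p = np.full((k, k), 0.15 / (k - 1) if k > 1 else 0.0)
    np.fill_diagonal(p, 0.85 if k > 1 else 1.0)
    return p


def generate_ndvi(config: SyntheticConfig) -> Raster:
    """Radially decaying NDVI field with optional Gaussian noise.

    The deterministic profile is ``v(d) = v0 * exp(-radial_decay * d)``
    with ``d`` the Euclidean distance from the oasis centre in cells, so
    the field crosses any threshold in (0, v0) exactly once and zonation
    recovers concentric rings.  Values are clipped to [-1, 1].
    """
    rows, cols = config.grid_shape
    r0, c0 = config.oasis_center
    rr, cc = np.mgrid[0:rows, 0:cols]
    d = np.hypot(rr - r0, cc - c0)
    ndvi = config.center_value * np.exp(-config.radial_decay * d)
    if config.noise_sd > 0:
        ndvi = ndvi + config.rng(1).normal(0.0, config.noise_sd, size=ndvi.shape)
    return Raster(np.clip(ndvi, -1.0, 1.0), cell_size=config.cell_size)


def _initial_landuse(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Patchy initial class map: smoothed per-class noise, argmax."""
    rows, cols = config.grid_shape
    fields = rng.normal(size=(config.n_classes, rows, cols))
    sigma = max(2.0, min(rows, cols) / 40.0)
    smoothed = np.stack([ndimage.gaussian_filter(f, sigma) for f in fields])
    return np.argmax(smoothed, axis=0).astype(np.int64) + 1


def _majority_filter(classes: np.ndarray, n_classes: int) -> np.ndarray:
    """3x3 modal filter; ties broken toward the lowest class code."""
    counts = np.zeros((n_classes,) + classes.shape, dtype=np.int32)
    kernel = np.ones((3, 3), dtype=np.int32)
    for c in range(1, n_classes + 1):
        counts[c - 1] = ndimage.convolve(
            (classes == c).astype(np.int32), kernel, mode="nearest"
        )
    return np.argmax(counts, axis=0).astype(np.int64) + 1


def generate_landuse_series(
    config: SyntheticConfig, smooth: bool = True
) -> list[Raster]:
    """Categorical land-use rasters evolved by a per-cell Markov chain.

    Epoch ``t+1`` is drawn cell-wise from row ``class_t`` of ``markov_P``;
    with ``smooth=True`` a single 3x3 majority filter follows each step to
    aggregate cells into contiguous patches.  Disable smoothing when the
    empirical transition frequencies must match ``markov_P`` exactly in
    expectation (the filter is a spatial interaction the chain does not
    model).
    """
    rng = config.rng(2)
    k = config.n_classes
    cum = np.cumsum(config.markov_P, axis=1)
    current = _initial_landuse(config, rng)
    epochs = [current]
    for _ in range(config.n_epochs - 1):
        u = rng.random(size=current.shape)
        # inverse-CDF draw from the row of P selected by each cell's class
        nxt = (u[..., None] > cum[current - 1]).sum(axis=-1).astype(np.int64) + 1
        nxt = np.minimum(nxt, k)
        if smooth:
            nxt = _majority_filter(nxt, k)
        epochs.append(nxt)
        current = nxt
    return [
        Raster(e, cell_size=config.cell_size, nodata=None) for e in epochs
    ]


def _minmax01(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    return np.zeros_like(x) if span == 0 else (x - x.min()) / span


def generate_driver_table(config: SyntheticConfig, n_rows: int) -> pd.DataFrame:
    """Driver table with a planted linear response.

    Each of the nine predictors is drawn independently on its natural
    scale; the ``eri`` response is the ``driver_effects``-weighted sum of
    the min-max-normalized predictors plus Gaussian noise, so predictors
    with zero effect are pure noise relative to the response.
    """
    if n_rows <= 0:
        raise ValueError("n_rows must be positive")
    rng = config.rng(3)
    cols: dict[str, np.ndarray] = {}
    for name in DRIVER_NAMES:
        loc, scale = _DRIVER_SCALES[name]
        vals = rng.normal(loc, scale, size=n_rows)
        cols[name] = np.maximum(vals, 0.0)
    response = np.zeros(n_rows)
    for name, effect in config.driver_effects.items():
        response += effect * _minmax01(cols[name])
    if config.driver_noise_sd > 0:
        response += rng.normal(0.0, config.driver_noise_sd, size=n_rows)
    table = pd.DataFrame(cols)
    table["eri"] = response
    return table


def generate_drivers(config: SyntheticConfig, risk) -> pd.DataFrame:
    """Driver table aligned with a risk grid (one row per sampling cell)."""
    n = len(risk.cells)
    if n < 50:
        raise ValueError(f"risk grid has {n} cells; need at least 50")
    return generate_driver_table(config, n)
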