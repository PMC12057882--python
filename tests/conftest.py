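"""Shared fixtures: published reference tables and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from oasisrisk.raster import Raster

# Published classification-accuracy counts for the oasis/transition/desert
# zonation (reference study, 2000 validation points per epoch; rows = mapped
# class, columns = reference class) with the accuracies printed alongside.
PRINTED_CONFUSION = {
    1990: ([[536, 66, 3], [34, 436, 54], [16, 33, 822]], 0.90, 0.84),
    2000: ([[566, 41, 7], [49, 388, 30], [29, 29, 861]], 0.91, 0.86),
    2010: ([[748, 21, 15], [43, 382, 40], [16, 41, 694]], 0.91, 0.86),
    2020: ([[1024, 26, 23], [23, 273, 44], [9, 35, 514]], 0.92, 0.86),
}

# Published belt and land-use areas (km^2) with the printed percent changes.
PRINTED_CHANGES = [
    # (area_t0, area_t1, printed percent, decimals printed)
    (146.3, 73.6, -49.7, 1),    # transition belt, 1990 -> 2020
    (257.8, 160.0, -37.9, 1),   # desert belt, 1990 -> 2020
    (247.48, 348.56, 40.84, 2),  # cropland, 1990 -> 2020
    (8.37, 37.02, 342.29, 2),    # built-up land, 1990 -> 2020
    (16.94, 10.57, -37.60, 2),   # forest land, 1990 -> 2020
]


@pytest.fixture
def printed_confusion():
    return PRINTED_CONFUSION


@pytest.fixture
def printed_changes():
    return PRINTED_CHANGES


def flood_fill_count(classes: np.ndarray, code: int, connectivity: int) -> int:
    """Brute-force connected-component count by BFS (oracle)."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    nrows, ncols = classes.shape
    seen = np.zeros_like(classes, dtype=bool)
    count = 0
    for r in range(nrows):
        for c in range(ncols):
            if classes[r, c] != code or seen[r, c]:
                continue
            count += 1
            stack = [(r, c)]
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                for dr, dc in offsets:
                    nr, nc = rr + dr, cc + dc
                    if (
                        0 <= nr < nrows
                        and 0 <= nc < ncols
                        and not seen[nr, nc]
                        and classes[nr, nc] == code
                    ):
                        seen[nr, nc] = True
                        stack.append((nr, nc))
    return count


def lattice_grid(nrows: int, ncols: int):
    """Full RiskGrid lattice of nrows x ncols unit cells (for weights tests)."""
    from oasisrisk.landscape_risk import RiskGrid

    cells = pd.DataFrame(
        [
            {"grow": r, "gcol": c, "area_km2": 1.0}
            for r in range(nrows)
            for c in range(ncols)
        ]
    )
    return RiskGrid(cells, grid_size_m=1000.0, class_names=[])


def categorical_raster(array, cell_size=1000.0, nodata=None) -> Raster:
    return Raster(np.asarray(array, dtype=np.int64), cell_size=cell_size, nodata=nodata)
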