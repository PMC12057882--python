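"""NDVI threshold zonation and classification accuracy scoring.

An arid-zone settlement is partitioned into three concentric belts by
vegetation cover: the oasis core (NDVI >= 0.30), the transition belt
(0.10 < NDVI < 0.30) and the surrounding desert (NDVI <= 0.10).  The
thresholds are the conventional ones for Landsat-derived NDVI in this
setting and both boundaries are assigned per the inclusive inequalities
above (0.30 -> oasis, 0.10 -> desert).

Classification quality against labelled reference points is summarised by
a confusion matrix and the standard remote-sensing accuracy statistics:
overall accuracy, Cohen's kappa, and per-class user's and producer's
accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster

__all__ = [
    "ZoneThresholds",
    "ZONE_CODES",
    "ZONE_LABELS",
    "ConfusionMatrix",
    "classify_zones",
    "confusion_matrix",
    "accuracy_metrics",
    "zone_areas",
]

ZONE_CODES = {"oasis": 1, "transition": 2, "desert": 3}
ZONE_LABELS = {v: k for k, v in ZONE_CODES.items()}
_ZONE_NODATA = 255


@dataclass(frozen=True)
class ZoneThresholds:
    """NDVI cutpoints delimiting the three belts (stored as fractions)."""

    oasis_min: float = 0.30
    desert_max: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 <= self.desert_max < self.oasis_min <= 1.0):
            raise ValueError(
                f"need 0 <= desert_max < oasis_min <= 1, got "
                f"desert_max={self.desert_max}, oasis_min={self.oasis_min}"
            )

    @classmethod
    def from_percent(cls, oasis_min: float, desert_max: float) -> "ZoneThresholds":
        """Parse thresholds given in percent (e.g. 30 -> 0.30)."""
        return cls(oasis_min / 100.0, desert_max / 100.0)


def classify_zones(ndvi: Raster, thresholds: ZoneThresholds | None = None) -> Raster:
    """Assign each NDVI cell to oasis (1), transition (2) or desert (3).

    Nodata propagates; a cell at exactly ``oasis_min`` is oasis and at
    exactly ``desert_max`` is desert.
    """
    thresholds = thresholds or ZoneThresholds()
    valid = ndvi.mask()
    data = np.asarray(ndvi.data, dtype=float)
    zones = np.full(data.shape, _ZONE_NODATA, dtype=np.int64)
    zones[valid] = ZONE_CODES["transition"]
    zones[valid & (data >= thresholds.oasis_min)] = ZONE_CODES["oasis"]
    zones[valid & (data <= thresholds.desert_max)] = ZONE_CODES["desert"]
    out = ndvi.like(zones, nodata=_ZONE_NODATA)
    out.labels = dict(ZONE_LABELS)
    return out


def zone_areas(zones: Raster) -> pd.Series:
    """Area (km^2) of each belt; the three entries sum to the study area."""
    areas = {}
    for name, code in ZONE_CODES.items():
        areas[name] = float((zones.data == code).sum()) * zones.cell_area_km2
    return pd.Series(areas)


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of mapped vs reference class at sample points.

    ``counts`` rows are the mapped class, columns the reference class.
    """

    counts: pd.DataFrame
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix has no usable points")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def confusion_matrix(zones: Raster, reference: pd.DataFrame) -> ConfusionMatrix:
    """Tabulate mapped zone against reference label at sample points.

    ``reference`` needs columns ``row``, ``col`` (0-based cell indices,
    origin top-left, nearest-cell-centre convention) and ``label`` (zone
    codes).  Points outside the raster or on nodata cells are skipped and
    counted in ``n_skipped``.
    """
    labels = sorted(ZONE_CODES.values())
    names = [ZONE_LABELS[c] for c in labels]
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    nrows, ncols = zones.shape
    skipped = 0
    for row, col, ref in reference[["row", "col", "label"]].itertuples(index=False):
        r, c = int(row), int(col)
        if not (0 <= r < nrows and 0 <= c < ncols):
            skipped += 1
            continue
        mapped = int(zones.data[r, c])
        if mapped not in ZONE_LABELS or int(ref) not in ZONE_LABELS:
            skipped += 1
            continue
        counts.loc[ZONE_LABELS[mapped], ZONE_LABELS[int(ref)]] += 1
    if skipped:
        warnings.warn(f"skipped {skipped} unusable sample points", stacklevel=2)
    return ConfusionMatrix(counts, n_skipped=skipped)


def accuracy_metrics(cm: ConfusionMatrix, orientation: str = "rows-map") -> dict:
    """Overall accuracy, kappa, and per-class user's/producer's accuracy.

    With ``orientation="rows-map"`` (default) rows of the matrix are the
    mapped class, so UA_i = diag_i / rowsum_i and PA_i = diag_i / colsum_i;
    ``"rows-reference"`` swaps the two.  OA and kappa are orientation
    invariant.  A class with an empty row or column gets NaN for the
    corresponding accuracy rather than 0.
    """
    if orientation not in {"rows-map", "rows-reference"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    m = cm.counts.to_numpy(dtype=float)
    total = m.sum()
    diag = np.diag(m)
    rowsum = m.sum(axis=1)
    colsum = m.sum(axis=0)
    oa = diag.sum() / total
    pe = float((rowsum * colsum).sum()) / total**2
    kappa = (oa - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        by_row = np.where(rowsum > 0, diag / rowsum, np.nan)
        by_col = np.where(colsum > 0, diag / colsum, np.nan)
    if orientation == "rows-map":
        ua, pa = by_row, by_col
    else:
        ua, pa = by_col, by_row
    classes = list(cm.counts.index)
    return {
        "OA": float(oa),
        "Kappa": float(kappa),
        "UA": dict(zip(classes, (float(v) for v in ua))),
        "PA": dict(zip(classes, (float(v) for v in pa))),
        "n": int(total),
    }
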