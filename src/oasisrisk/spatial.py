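"""Spatial autocorrelation of the risk surface: global and local Moran.

The global Moran's I over sampling cells,

    I = n * sum_ij w_ij (x_i - xbar)(x_j - xbar)
        / (S0 * sum_i (x_i - xbar)^2),        S0 = sum_ij w_ij,

measures whether similar risk values cluster in space (I near +1),
alternate (near -1) or are arranged at random (near the permutation-null
expectation -1/(n-1)).  The local decomposition

    I_i = n (x_i - xbar) * sum_j w_ij (x_j - xbar) / sum_i (x_i - xbar)^2

satisfies sum_i I_i / S0 = I exactly, and its sign quadrant — the cell's
deviation vs its neighbourhood's — types each significant cell as a
High-High, High-Low, Low-High or Low-Low cluster (LISA).  Significance is
by conditional permutation: hold x_i fixed, redraw its neighbours' values
from the remaining cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .landscape_risk import RiskGrid

__all__ = ["SpatialWeights", "MoranResult", "build_weights", "global_moran", "local_moran"]


@dataclass
class SpatialWeights:
    """Contiguity weights over grid cells.

    ``matrix`` is sparse with zero diagonal; rook contiguity joins cells
    sharing an edge, queen also joins corner neighbours.  Row
    standardization divides each row by its neighbour count (islands keep
    all-zero rows).
    """

    matrix: sparse.csr_matrix
    scheme: str
    standardization: str

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())

    def neighbor_counts(self) -> np.ndarray:
        return np.asarray((self.matrix != 0).sum(axis=1)).ravel()


def build_weights(
    grid: RiskGrid, scheme: str = "queen", standardization: str = "row"
) -> SpatialWeights:
    """Contiguity weights between the cells of a sampling grid."""
    if scheme not in {"queen", "rook"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    if standardization not in {"row", "binary"}:
        raise ValueError(f"unknown standardization {standardization!r}")
    cells = grid.cells
    n = len(cells)
    if n < 2:
        raise ValueError("need at least two cells to build weights")
    index = {
        (int(r), int(c)): i
        for i, (r, c) in enumerate(zip(cells["grow"], cells["gcol"]))
    }
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows, cols = [], []
    for (r, c), i in index.items():
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
    w = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=float
    )
    if standardization == "row":
        deg = np.asarray(w.sum(axis=1)).ravel()
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        w = sparse.diags(inv) @ w
    return SpatialWeights(w.tocsr(), scheme=scheme, standardization=standardization)


def global_moran(x: np.ndarray, w: SpatialWeights) -> float:
    """Global Moran's I; raises on a constant field (I is undefined)."""
    x = np.asarray(x, dtype=float)
    if x.size != w.n:
        raise ValueError("value vector length does not match weights")
    if x.size < 2:
        raise ValueError("need at least two observations")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I is undefined for a constant field")
    num = float(z @ (w.matrix @ z))
    return x.size * num / (w.s0 * denom)


@dataclass
class MoranResult:
    """Global I, its null expectation, and per-cell LISA statistics."""

    I_global: float
    expected: float
    local_i: np.ndarray
    pseudo_p: np.ndarray
    cluster: np.ndarray  # 'HH' | 'HL' | 'LH' | 'LL' | 'ns'
    lag: np.ndarray


def local_moran(
    x: np.ndarray,
    w: SpatialWeights,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> MoranResult:
    """Local Moran statistics with conditional-permutation inference.

    Cluster labels are assigned only where the pseudo-p (the proportion of
    permuted local statistics at least as extreme as the observed one, in
    its direction) is at or below ``alpha``.  Islands have zero lag and are
    never significant.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be at least 99")
    x = np.asarray(x, dtype=float)
    n = x.size
    z = x - x.mean()
    m2 = float(z @ z)
    if m2 == 0.0:
        raise ValueError("local Moran is undefined for a constant field")
    lag = w.matrix @ z
    local_i = n * z * lag / m2
    k = w.neighbor_counts()

    rng = np.random.default_rng(seed)
    pseudo_p = np.ones(n)
    W = w.matrix
    for i in range(n):
        ki = int(k[i])
        if ki == 0:
            continue  # island
        wvals = W.data[W.indptr[i] : W.indptr[i + 1]]
        others = np.delete(z, i)
        # draw ki distinct neighbours per permutation via random-key selection
        keys = rng.random((n_permutations, others.size))
        pick = np.argpartition(keys, ki - 1, axis=1)[:, :ki]
        sim_lag = others[pick] @ wvals
        sim_i = n * z[i] * sim_lag / m2
        larger = int((sim_i >= local_i[i]).sum())
        larger = min(larger, n_permutations - larger)
        pseudo_p[i] = (larger + 1) / (n_permutations + 1)

    cluster = np.full(n, "ns", dtype=object)
    sig = (pseudo_p <= alpha) & (k > 0)
    cluster[sig & (z > 0) & (lag > 0)] = "HH"
    cluster[sig & (z > 0) & (lag < 0)] = "HL"
    cluster[sig & (z < 0) & (lag > 0)] = "LH"
    cluster[sig & (z < 0) & (lag < 0)] = "LL"
    return MoranResult(
        I_global=global_moran(x, w),
        expected=-1.0 / (n - 1),
        local_i=local_i,
        pseudo_p=pseudo_p,
        cluster=cluster.astype(str),
        lag=np.asarray(lag),
    )
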