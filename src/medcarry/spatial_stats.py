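"""Bivariate local Moran's I (LISA) with conditional permutation inference.

The bivariate local Moran statistic relates a unit's own value of one
variable (here: hospital supply level) to the spatial lag — the
weighted neighborhood average — of another (population):

    I_i = z_x,i * sum_j w_ij z_y,j

with z-scores using the population (1/n) standard deviation and
row-standardized spatial weights.  Positive I_i marks local spatial
agreement (high supply amid high population, or low amid low), negative
I_i local mismatch.  Significance comes from conditional permutation:
unit i's own value is held fixed while the other variable is permuted over
the remaining units, giving a pseudo p-value with the +1 correction.
Significant units are labeled HH / HL / LH / LL by the signs of z_x,i and
of the observed lag of z_y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SpatialWeights",
    "build_knn_weights",
    "build_queen_weights",
    "bivariate_local_moran",
    "permutation_test",
]


@dataclass
class SpatialWeights:
    """Sparse row-standardized neighbor weights.

    ``neighbors[i]`` is an int array of neighbor indices of unit i (never
    containing i itself); ``weights[i]`` the matching weight array.  When
    row-standardized, each non-isolated row sums to 1; isolated units
    (no neighbors) keep an empty row and are flagged.
    """

    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    row_standardized: bool = True

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def isolated(self) -> np.ndarray:
        return np.array([len(nb) == 0 for nb in self.neighbors])

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Spatial lag ``(Wz)_i = sum_j w_ij z_j`` (0 for isolated units)."""
        z = np.asarray(z, dtype=float)
        return np.array(
            [
                w @ z[nb] if len(nb) else 0.0
                for nb, w in zip(self.neighbors, self.weights)
            ]
        )

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n, self.n))
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            out[i, nb] = w
        return out


def _row_standardize(neighbors: list[np.ndarray]) -> SpatialWeights:
    weights = [
        np.full(len(nb), 1.0 / len(nb)) if len(nb) else np.empty(0)
        for nb in neighbors
    ]
    return SpatialWeights(neighbors=neighbors, weights=weights)


def build_knn_weights(coords: np.ndarray, k: int = 8) -> SpatialWeights:
    """k-nearest-neighbor weights from unit coordinates (row-standardized).

    Neighbor relations may be asymmetric (A's nearest neighbor need not
    have A among its own k nearest).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units")
    if k >= n:
        raise ValueError(f"k = {k} must be < number of units n = {n}")
    tree = cKDTree(coords)
    # query k+1 then drop self
    _, idx = tree.query(coords, k=k + 1)
    neighbors = []
    for i in range(n):
        nb = [j for j in np.atleast_1d(idx[i]) if j != i][:k]
        neighbors.append(np.asarray(nb, dtype=int))
    return _row_standardize(neighbors)


def build_queen_weights(rows: np.ndarray, cols: np.ndarray) -> SpatialWeights:
    """Queen contiguity on grid cells given integer (row, col) indices.

    Two cells are neighbors when their row and column indices each differ
    by at most 1 (8-neighborhood).  Row-standardized.
    """
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    n = rows.size
    if n < 2:
        raise ValueError("need at least 2 units")
    index = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    neighbors = []
    for r, c in zip(rows, cols):
        nb = [
            index[(r + dr, c + dc)]
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if not (dr == 0 and dc == 0) and (r + dr, c + dc) in index
        ]
        neighbors.append(np.asarray(sorted(nb), dtype=int))
    return _row_standardize(neighbors)


def _zscore(v: np.ndarray, population_sd: bool = True) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=0 if population_sd else 1)
    if sd == 0:
        raise ValueError("zero variance input")
    return (v - v.mean()) / sd


def bivariate_local_moran(
    x: np.ndarray,
    y: np.ndarray,
    w: SpatialWeights,
    population_sd: bool = True,
) -> np.ndarray:
    """Bivariate local Moran ``I_i = z_x,i * (W z_y)_i`` per unit.

    With ``y is x`` this reduces to the univariate local Moran, whose mean
    equals the global Moran's I under row-standardized weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (w.n,) or y.shape != (w.n,):
        raise ValueError("x, y must align with the weights")
    zx = _zscore(x, population_sd)
    zy = _zscore(y, population_sd)
    return zx * w.lag(zy)


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.01,
    population_sd: bool = True,
) -> pd.DataFrame:
    """Conditional permutation inference for the bivariate local Moran.

    For each unit i, z_x,i is held fixed while the y values of the other
    n-1 units are randomly reassigned to i's neighbors ``n_perm`` times;
    the two-sided pseudo p-value is
    ``(count(|I_perm| >= |I_obs|) + 1) / (n_perm + 1)``.

    Returns a DataFrame with columns ``I`` (observed statistic), ``p``
    (pseudo p-value), ``quadrant`` (HH/HL/LH/LL from the signs of z_x,i
    and the observed lag of z_y), and ``label`` (the quadrant when
    p <= alpha, else "not-significant"; isolated units are always
    "not-significant").
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = w.n
    zx = _zscore(x, population_sd)
    zy = _zscore(y, population_sd)
    lag_obs = w.lag(zy)
    i_obs = zx * lag_obs

    rng = np.random.default_rng(seed)
    # shared pool of permutations of the n-1 "other" positions; for unit i
    # the first k_i entries index into the other units' z_y values.
    rids = np.array([rng.permutation(n - 1) for _ in range(n_perm)])

    others = np.arange(n)
    p = np.ones(n)
    for i in range(n):
        nb = w.neighbors[i]
        k = len(nb)
        if k == 0:
            continue
        pool = np.delete(others, i)
        draw = zy[pool[rids[:, :k]]]  # (n_perm, k)
        lag_perm = draw @ w.weights[i]
        i_perm = zx[i] * lag_perm
        extreme = np.count_nonzero(np.abs(i_perm) >= np.abs(i_obs[i]))
        p[i] = (extreme + 1) / (n_perm + 1)

    quadrant = np.where(
        zx > 0,
        np.where(lag_obs > 0, "HH", "HL"),
        np.where(lag_obs > 0, "LH", "LL"),
    ).astype(object)
    significant = (p <= alpha) & ~w.isolated
    label = np.where(significant, quadrant, "not-significant").astype(object)
    return pd.DataFrame(
        {"I": i_obs, "p": p, "quadrant": quadrant, "label": label}
    )
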