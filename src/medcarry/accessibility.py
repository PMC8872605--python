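"""Kernel-decay two-step floating catchment area (2SFCA) carrying capacity.

The carrying-capacity index of a demand zone summarises how much hospital
supply is reachable per person within a catchment threshold ``d0``:

* step 1 — each supply point j gets a supply-to-demand ratio
  ``R_j = S_j / sum_{k: d_kj <= d0} G(d_kj) * D_k``, where demand within the
  catchment is discounted by the concave kernel
  ``G(d) = (3/4) * (1 - (d/d0)^2)``;
* step 2 — each demand point i sums the ratios of reachable supply points,
  ``A_i = sum_{j: d_ij <= d0} R_j`` ("paper" mode) or the kernel-weighted
  sum ``A_i = sum G(d_ij) R_j`` ("symmetric" mode, the common variant that
  decays both steps and conserves total supply).

``d0`` defaults to the maximum over demand points of the distance to the
nearest supply point, which guarantees every demand point can reach at
least one supply point.

Capacity values are graded into five levels (lower, low, middle, high,
higher) with exact Jenks natural breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ODMatrix",
    "compute_threshold",
    "kernel_weight",
    "step1_ratios",
    "step2_capacity",
    "jenks_breaks",
    "classify_capacity",
    "CAPACITY_GRADE_LABELS",
]

#: grade labels for the five-class capacity grading, lowest to highest
CAPACITY_GRADE_LABELS = ("lower", "low", "middle", "high", "higher")

Mode = Literal["paper", "symmetric"]


@dataclass
class ODMatrix:
    """Origin-destination network distances, demand rows x supply columns.

    ``values[i, j]`` is the shortest-path distance from demand point
    ``demand_ids[i]`` to supply point ``supply_ids[j]``.  Complete over the
    cross product and nonnegative.
    """

    demand_ids: list = field(default_factory=list)
    supply_ids: list = field(default_factory=list)
    values: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.demand_ids), len(self.supply_ids)):
            raise ValueError("distance array shape does not match id lists")
        if self.values.size and np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_long_frame(self) -> pd.DataFrame:
        """Long CSV-friendly form: demand_id, supply_id, distance."""
        nd, ns = self.values.shape
        return pd.DataFrame(
            {
                "demand_id": np.repeat(self.demand_ids, ns),
                "supply_id": np.tile(self.supply_ids, nd),
                "distance": self.values.ravel(),
            }
        )

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "ODMatrix":
        wide = frame.pivot(
            index="demand_id", columns="supply_id", values="distance"
        )
        if wide.isna().any().any():
            raise ValueError("OD table is not complete over the cross product")
        return cls(
            demand_ids=list(wide.index),
            supply_ids=list(wide.columns),
            values=wide.to_numpy(dtype=float),
        )


def compute_threshold(od: ODMatrix, side: str = "demand") -> float:
    """Catchment threshold d0 from an OD matrix.

    Default (``side="demand"``) is the maximum over demand points of the
    distance to the nearest supply point — every demand point then has at
    least one supply point within d0.  ``side="supply"`` gives the
    transposed reading (max over supply points of the nearest demand).
    """
    if od.values.size == 0:
        raise ValueError("empty OD matrix")
    if side == "demand":
        return float(od.values.min(axis=1).max())
    if side == "supply":
        return float(od.values.min(axis=0).max())
    raise ValueError(f"unknown side {side!r}")


def kernel_weight(d, d0: float):
    """Concave kernel distance-decay weight.

    ``G(d) = (3/4) (1 - (d/d0)^2)`` for ``d <= d0`` and 0 beyond, so
    ``G(0) = 0.75``, ``G(d0) = 0``, strictly decreasing on [0, d0].  The
    degenerate ``d0 = 0`` (every demand point colocated with its nearest
    supply) falls back to an indicator weight: 1 at d = 0, else 0.

    Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative distance")
    if d0 < 0:
        raise ValueError("negative threshold")
    if d0 == 0:
        out = np.where(d == 0, 1.0, 0.0)
    else:
        out = np.where(d <= d0, 0.75 * (1.0 - (d / d0) ** 2), 0.0)
    return float(out) if out.ndim == 0 else out


def step1_ratios(
    supply: pd.Series | np.ndarray | Sequence[float],
    demand: pd.Series | np.ndarray | Sequence[float],
    od: ODMatrix,
    d0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Supply-to-demand ratio R_j per supply point (2SFCA step 1).

    ``R_j = S_j / sum_{k: d_kj <= d0} G(d_kj) D_k``.  A supply point whose
    kernel-weighted in-catchment demand is zero (no demand in range, or all
    of it exactly at distance d0) gets ``R_j = 0`` and is flagged.

    Returns
    -------
    (ratios, empty_catchment)
        ``ratios`` — R_j array over supply points; ``empty_catchment`` —
        boolean flags for supply points with zero weighted demand.
    """
    s = np.asarray(supply, dtype=float)
    dk = np.asarray(demand, dtype=float)
    if np.any(s < 0):
        raise ValueError("supply scores must be nonnegative")
    if np.any(dk <= 0):
        raise ValueError("demand populations must be positive")
    nd, ns = od.shape
    if s.shape != (ns,) or dk.shape != (nd,):
        raise ValueError("supply/demand lengths do not match OD matrix")

    g = kernel_weight(od.values, d0)  # (nd, ns)
    weighted_demand = (g * dk[:, None]).sum(axis=0)
    empty = weighted_demand == 0
    ratios = np.where(empty, 0.0, s / np.where(empty, 1.0, weighted_demand))
    return ratios, empty


def step2_capacity(
    ratios: np.ndarray,
    od: ODMatrix,
    d0: float,
    mode: Mode = "paper",
) -> np.ndarray:
    """Carrying-capacity index A_i per demand point (2SFCA step 2).

    ``mode="paper"`` (default): plain sum of reachable ratios,
    ``A_i = sum_{j: d_ij <= d0} R_j`` — the kernel discounts only step 1.
    ``mode="symmetric"``: ``A_i = sum_j G(d_ij) R_j`` — both steps decay,
    which makes total demand-weighted capacity conserve total supply when
    every supply point has in-range demand.
    """
    ratios = np.asarray(ratios, dtype=float)
    nd, ns = od.shape
    if ratios.shape != (ns,):
        raise ValueError("ratio length does not match OD matrix")
    if mode == "paper":
        reach = (od.values <= d0).astype(float)
        return reach @ ratios
    if mode == "symmetric":
        return kernel_weight(od.values, d0) @ ratios
    raise ValueError(f"unknown mode {mode!r}")


def jenks_breaks(values: Sequence[float] | np.ndarray, n_classes: int) -> list[float]:
    """Exact Jenks natural breaks (optimal 1-D classification).

    Partitions the sorted values into ``n_classes`` contiguous classes
    minimizing the total within-class sum of squared deviations from the
    class means, by dynamic programming (Fisher's exact algorithm,
    O(k n^2)).  Returns ``n_classes + 1`` edges
    ``[min, b_1, ..., b_{k-1}, max]`` where each interior break is the
    lowest value of the class above it.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n_classes < 1:
        raise ValueError("need at least one class")
    if np.unique(x).size < n_classes:
        raise ValueError(
            f"need at least {n_classes} distinct values, got {np.unique(x).size}"
        )

    # prefix sums for O(1) within-class SSD of x[i:j]
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csq = np.concatenate(([0.0], np.cumsum(x * x)))

    def ssd(i: int, j: int) -> float:
        # SSD of x[i:j], j exclusive
        m = j - i
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / m

    INF = np.inf
    # cost[j]: min SSD partitioning x[:j] into the current class count
    choice = np.zeros((n_classes + 1, n + 1), dtype=int)
    cost = np.full(n + 1, INF)
    cost[1:] = [ssd(0, j) for j in range(1, n + 1)]
    for c in range(2, n_classes + 1):
        new = np.full(n + 1, INF)
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[i] + ssd(i, j)
                if v < best - 1e-12:
                    best, arg = v, i
            new[j] = best
            choice[c][j] = arg
        cost = new

    # walk back the split points
    splits = []
    j = n
    for c in range(n_classes, 1, -1):
        i = choice[c][j]
        splits.append(i)
        j = i
    splits.reverse()
    edges = [float(x[0])] + [float(x[i]) for i in splits] + [float(x[-1])]
    return edges


def classify_capacity(
    values: Sequence[float] | np.ndarray,
    n_classes: int = 5,
    labels: Sequence[str] | None = None,
) -> tuple[list[float], np.ndarray]:
    """Grade capacity values by Jenks natural breaks.

    Classes are half-open ``[b_k, b_{k+1})`` except the top class, which is
    closed.  Labels run lowest to highest; the default five-class labels
    are ``lower, low, middle, high, higher``.

    Returns
    -------
    (breaks, labels_per_value)
    """
    x = np.asarray(values, dtype=float)
    if labels is None:
        if n_classes == 5:
            labels = CAPACITY_GRADE_LABELS
        else:
            labels = [f"class_{i + 1}" for i in range(n_classes)]
    if len(labels) != n_classes:
        raise ValueError("label count must equal n_classes")
    edges = jenks_breaks(x, n_classes)
    # np.digitize with right=False puts x == interior edge into the upper
    # class; clip the top so the maximum stays in the last class (closed).
    idx = np.digitize(x, edges[1:-1], right=False)
    idx = np.clip(idx, 0, n_classes - 1)
    return edges, np.asarray(labels, dtype=object)[idx]
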