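"""Coupling coordination degree (CCD) of supply and demand over time.

Two subsystem indices per year — a supply level X and a demand level Y,
each an entropy-weighted composite of its indicator layer — are combined
into:

* coupling degree  ``C = [4 X Y / (X + Y)^2]^k``  (k = 2 by default), which
  is 1 exactly when X = Y > 0 and falls toward 0 as the two diverge;
* comprehensive index  ``T = alpha X + beta Y``  (alpha = beta = 0.5), the
  overall level of the joint system;
* coupling coordination degree  ``D = sqrt(C * T)``, banded into eight
  coordination grades from "Disordered" (D < 0.3) up to "Better
  coordination" (D >= 0.9).

The radical form of D is the default; the plain product ``D = C * T`` is
available via ``radical=False``.
"""

from __future__ import annotations

import math

import pandas as pd

from medcarry.weighting import composite_score, entropy_weights, min_max_normalize

__all__ = [
    "coupling_degree",
    "comprehensive_index",
    "coupling_coordination",
    "classify_ccd",
    "ccd_series",
    "CCD_BANDS",
]

#: coordination-grade bands of D: (lower edge, label); each band is
#: half-open [lo, hi) except the top one, which includes D = 1.
CCD_BANDS = (
    (0.0, "Disordered"),
    (0.3, "On the verge of disorder"),
    (0.4, "Reluctantly coordinated"),
    (0.5, "Low coordination"),
    (0.6, "Primary coordination"),
    (0.7, "Middle coordination"),
    (0.8, "Good coordination"),
    (0.9, "Better coordination"),
)


def coupling_degree(x: float, y: float, k: float = 2.0) -> float:
    """Coupling degree C of a two-subsystem (X, Y) pair.

    ``C = [X Y / ((X+Y)/2)^2]^k = [4XY/(X+Y)^2]^k`` lies in [0, 1] and
    equals 1 iff X = Y > 0.  Both-zero input is the "no system present"
    convention C := 0 (the limit along X = Y -> 0+ would be 1; the zero
    choice is deliberate and documented).
    """
    if x < 0 or y < 0:
        raise ValueError("subsystem levels must be nonnegative")
    if x == 0 and y == 0:
        return 0.0
    return float((4.0 * x * y / (x + y) ** 2) ** k)


def comprehensive_index(
    x: float, y: float, alpha: float = 0.5, beta: float = 0.5
) -> float:
    """Comprehensive evaluation index ``T = alpha X + beta Y``.

    The contribution weights must be nonnegative and sum to 1.
    """
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > 1e-9:
        raise ValueError("alpha, beta must be nonnegative and sum to 1")
    return float(alpha * x + beta * y)


def coupling_coordination(c: float, t: float, radical: bool = True) -> float:
    """Coupling coordination degree ``D = sqrt(C*T)`` (or ``C*T``)."""
    if c < 0 or t < 0:
        raise ValueError("C and T must be nonnegative")
    return float(math.sqrt(c * t)) if radical else float(c * t)


def classify_ccd(d: float) -> str:
    """Coordination-grade label of a coordination degree D in [0, 1].

    Bands are half-open from below ([0.3, 0.4) is "On the verge of
    disorder", so D = 0.3 falls in that band, not the one below); the top
    band [0.9, 1.0] is closed.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"D = {d} outside [0, 1]")
    label = CCD_BANDS[0][1]
    for lo, name in CCD_BANDS:
        if d >= lo:
            label = name
    return label


def ccd_series(
    panel: pd.DataFrame,
    layer_map: dict[str, str],
    k: float = 2.0,
    alpha: float = 0.5,
    beta: float = 0.5,
    radical: bool = True,
    renormalize_layers: bool = False,
) -> pd.DataFrame:
    """Per-year CCD results from a year x indicator panel.

    The panel is min-max normalized over years and entropy-weighted once
    over all indicators; the supply index X and demand index Y are the
    weighted composites over the columns that ``layer_map`` assigns to
    ``"supply"`` and ``"demand"`` respectively.

    Returns a DataFrame indexed like the panel with columns
    ``X, Y, C, T, D, grade``, plus the attribute
    ``result.attrs["crossover_year"]`` — the first index label where
    X > Y strictly (None if never).

    Raises
    ------
    KeyError
        If a panel column has no layer assignment.
    ValueError
        Propagated from the weighting step for all-constant panels.
    """
    missing = [c for c in panel.columns if c not in layer_map]
    if missing:
        raise KeyError(f"indicators without layer assignment: {missing}")
    supply_cols = [c for c in panel.columns if layer_map[c] == "supply"]
    demand_cols = [c for c in panel.columns if layer_map[c] == "demand"]
    if not supply_cols or not demand_cols:
        raise ValueError("both supply and demand layers must be non-empty")

    norm = min_max_normalize(panel)
    weights = entropy_weights(norm)
    x = composite_score(norm, weights, supply_cols, renormalize=renormalize_layers)
    y = composite_score(norm, weights, demand_cols, renormalize=renormalize_layers)

    rows = []
    for xi, yi in zip(x, y):
        c = coupling_degree(xi, yi, k=k)
        t = comprehensive_index(xi, yi, alpha=alpha, beta=beta)
        d = coupling_coordination(c, t, radical=radical)
        rows.append((xi, yi, c, t, d, classify_ccd(min(d, 1.0))))
    out = pd.DataFrame(
        rows, index=panel.index, columns=["X", "Y", "C", "T", "D", "grade"]
    )
    crossover = None
    for year, (xi, yi) in zip(panel.index, zip(x, y)):
        if xi > yi:
            crossover = year
            break
    out.attrs["crossover_year"] = crossover
    return out
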