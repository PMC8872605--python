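"""Entropy-weight scoring of indicator panels.

The entropy weight method assigns objective weights to indicators based on
their dispersion across observation units (years, or hospitals): an
indicator that varies a lot carries more information and receives a larger
weight, while a constant indicator is uninformative and receives weight
zero.

The panel is a :class:`pandas.DataFrame` whose rows are observation units
and whose columns are indicators, holding raw (unscaled) values.  The
workflow is

1. :func:`min_max_normalize` — rescale each column to [0, 1],
2. :func:`entropy_weights` — one weight per indicator, summing to 1,
3. :func:`composite_score` — weighted sum per row, optionally over a column
   subset (e.g. only supply-layer indicators).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = ["min_max_normalize", "entropy_weights", "composite_score"]


def min_max_normalize(
    panel: pd.DataFrame,
    orientation: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rescale each indicator column to [0, 1].

    Positive-orientation columns (the default; larger raw value = better)
    map ``v`` to ``(v - min) / (max - min)``; negative-orientation columns
    to ``(max - v) / (max - min)``.  A constant column (max == min) carries
    no information and is normalized to all zeros, so that it later
    receives entropy weight zero.

    Parameters
    ----------
    panel
        Raw indicator panel; numeric, no missing cells, at least 2 rows.
    orientation
        Optional mapping ``column -> "positive" | "negative"``.  Columns
        not listed are treated as positive.

    Returns
    -------
    DataFrame of the same shape with values in [0, 1].
    """
    if panel.shape[0] < 2:
        raise ValueError("panel needs at least 2 rows to normalize")
    if panel.isna().any().any():
        raise ValueError("panel contains missing cells")
    orientation = orientation or {}

    values = panel.to_numpy(dtype=float)
    vmin = values.min(axis=0)
    vmax = values.max(axis=0)
    span = vmax - vmin
    constant = span == 0
    span_safe = np.where(constant, 1.0, span)

    out = (values - vmin) / span_safe
    for j, col in enumerate(panel.columns):
        if orientation.get(col, "positive") == "negative":
            out[:, j] = np.where(constant[j], 0.0, 1.0 - out[:, j])
    out[:, constant] = 0.0
    return pd.DataFrame(out, index=panel.index, columns=panel.columns)


def entropy_weights(norm: pd.DataFrame) -> pd.Series:
    """Entropy weights from a min-max normalized panel.

    For indicator ``i`` over ``n`` units, with normalized values ``r``:
    shares ``f = r / sum(r)`` (uniform ``1/n`` when the column sum is 0,
    which yields maximal entropy and hence zero weight), entropy
    ``H_i = -(1/ln n) * sum(f ln f)`` with ``0 ln 0 := 0``, and weight
    ``w_i = (1 - H_i) / (m - sum(H))`` over the ``m`` indicators.

    Raises
    ------
    ValueError
        If every column is constant (no information anywhere).
    """
    r = norm.to_numpy(dtype=float)
    if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
        raise ValueError("panel does not look normalized to [0, 1]")
    n, m = r.shape
    colsum = r.sum(axis=0)
    zero_cols = colsum == 0
    f = np.where(zero_cols, 1.0 / n, r / np.where(zero_cols, 1.0, colsum))
    with np.errstate(divide="ignore", invalid="ignore"):
        flogf = np.where(f > 0, f * np.log(f), 0.0)
    entropy = -flogf.sum(axis=0) / np.log(n)
    # snap floating error: H is exactly 1 for uniform shares, and in [0, 1]
    entropy = np.clip(entropy, 0.0, 1.0)
    entropy[entropy > 1.0 - 1e-12] = 1.0

    divergence = 1.0 - entropy
    total = divergence.sum()
    if total <= 0:
        raise ValueError(
            "all indicators are constant: entropy weights undefined"
        )
    weights = divergence / total
    return pd.Series(weights, index=norm.columns, name="weight")


def composite_score(
    norm: pd.DataFrame,
    weights: pd.Series,
    columns: Sequence[str] | None = None,
    renormalize: bool = False,
) -> pd.Series:
    """Weighted composite score per row.

    ``score_row = sum_{i in columns} w_i * r_{row,i}``.  With the full
    column set and weights summing to 1 the score lies in [0, 1]; with a
    subset (e.g. only the supply layer) it lies in
    ``[0, sum of subset weights]`` unless ``renormalize`` rescales the
    subset weights to sum to 1.

    Parameters
    ----------
    norm
        Normalized panel.
    weights
        Weight per indicator (indexed by column name).
    columns
        Subset of columns to score over; default all panel columns.
    renormalize
        If True, divide the subset weights by their sum.
    """
    if columns is None:
        columns = list(norm.columns)
    columns = list(columns)
    if not columns:
        raise ValueError("empty column subset")
    missing = set(columns) - set(norm.columns)
    if missing:
        raise KeyError(f"columns not in panel: {sorted(missing)}")
    w = weights.loc[columns].to_numpy(dtype=float)
    if renormalize:
        total = w.sum()
        if total <= 0:
            raise ValueError("subset weights sum to zero")
        w = w / total
    scores = norm[columns].to_numpy(dtype=float) @ w
    return pd.Series(scores, index=norm.index, name="score")
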