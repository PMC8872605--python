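"""Inverse-distance-weighted (IDW) interpolation of point values to a grid.

Used to turn hospital-level supply scores (or workload) into a continuous
surface: each grid node takes the distance-weighted average of the data
points, ``v(g) = sum v_i d_i^-p / sum d_i^-p``, so the surface is a convex
combination of the data (never outside their range) and honors the data
exactly where a node coincides with a point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["idw_surface", "write_ascii_grid"]


def idw_surface(
    points: np.ndarray,
    values: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    power: float = 2.0,
    max_neighbors: int | None = None,
) -> np.ndarray:
    """IDW surface on the tensor grid ``grid_x`` x ``grid_y``.

    Parameters
    ----------
    points
        (n, 2) data coordinates.
    values
        (n,) data values.
    grid_x, grid_y
        1-D node coordinates; output has shape (len(grid_y), len(grid_x))
        with rows indexed by y (raster convention).
    power
        Decay exponent p > 0; larger p approaches nearest-neighbor
        assignment.
    max_neighbors
        If set, only the nearest ``max_neighbors`` points contribute at
        each node; default all points.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    if values.shape != (points.shape[0],):
        raise ValueError("values must align with points")
    if power <= 0:
        raise ValueError("power must be positive")
    gx, gy = np.meshgrid(np.asarray(grid_x, float), np.asarray(grid_y, float))
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    if nodes.size == 0:
        raise ValueError("empty grid")

    if max_neighbors is not None and max_neighbors < points.shape[0]:
        tree = cKDTree(points)
        dist, idx = tree.query(nodes, k=max_neighbors)
        dist = np.atleast_2d(dist)
        vals = values[np.atleast_2d(idx)]
    else:
        diff = nodes[:, None, :] - points[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        vals = np.broadcast_to(values, dist.shape)

    out = np.empty(nodes.shape[0])
    exact = dist == 0
    hit = exact.any(axis=1)
    # exact interpolation where a node sits on a data point
    if hit.any():
        first = exact[hit].argmax(axis=1)
        out[hit] = vals[hit, first] if vals.ndim == 2 else values[first]
    rest = ~hit
    if rest.any():
        w = dist[rest] ** (-power)
        out[rest] = (w * vals[rest]).sum(axis=1) / w.sum(axis=1)
    return out.reshape(gy.shape)


def write_ascii_grid(
    surface: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    path,
) -> None:
    """Write a surface as a plain gridded CSV (y rows x x columns)."""
    frame = pd.DataFrame(
        surface, index=pd.Index(grid_y, name="y"), columns=pd.Index(grid_x, name="x")
    )
    frame.to_csv(path)
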