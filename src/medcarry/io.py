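"""Plain-text readers and writers: CSV and GeoJSON point layers."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "write_geojson_points",
    "read_geojson_points",
]


def write_geojson_points(
    frame: pd.DataFrame,
    path,
    x: str = "x",
    y: str = "y",
) -> None:
    """Write a point DataFrame as a GeoJSON FeatureCollection.

    Every column except the coordinate columns becomes a feature property.
    """
    props = [c for c in frame.columns if c not in (x, y)]
    features = []
    for _, row in frame.iterrows():
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row[x]), float(row[y])],
                },
                "properties": {
                    c: (row[c].item() if hasattr(row[c], "item") else row[c])
                    for c in props
                },
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_geojson_points(path) -> pd.DataFrame:
    """Read a GeoJSON point FeatureCollection into a DataFrame.

    Coordinates land in columns ``x`` and ``y``; properties keep their
    names.
    """
    payload = json.loads(Path(path).read_text())
    rows = []
    for feat in payload["features"]:
        if feat["geometry"]["type"] != "Point":
            raise ValueError("only Point features are supported")
        gx, gy = feat["geometry"]["coordinates"][:2]
        rows.append({"x": gx, "y": gy, **feat.get("properties", {})})
    return pd.DataFrame(rows)
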