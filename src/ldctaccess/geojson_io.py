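"""Read/write polygon layers as GeoJSON FeatureCollections.

Layers travel in memory as pandas DataFrames with a shapely ``geometry``
column plus attribute columns.  Output is deterministic (sorted keys,
fixed separators) so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape


def write_layer(layer: pd.DataFrame, path: str | Path) -> None:
    features = []
    for _, row in layer.iterrows():
        props = {k: v for k, v in row.items() if k != "geometry"}
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(row["geometry"]),
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc, sort_keys=True, separators=(",", ":")))


def read_layer(path: str | Path) -> pd.DataFrame:
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    records = []
    for feat in fc["features"]:
        rec = dict(feat.get("properties") or {})
        rec["geometry"] = shape(feat["geometry"])
        records.append(rec)
    return pd.DataFrame.from_records(records)
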