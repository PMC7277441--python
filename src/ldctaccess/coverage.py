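"""Fixed-radius buffer coverage of census tracts.

Each provider gets a circular buffer of ``radius_miles`` (default 30) in
the planar equal-area system; a tract is *served* by a provider when
strictly more than ``threshold`` (default 0.51) of its area lies inside
the buffer.  Tract provider counts are the number of providers serving
the tract, and county counts are the sums over member tracts — a
provider serving k tracts of one county contributes k to that county.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

log = logging.getLogger(__name__)

DEFAULT_RADIUS_MILES = 30.0
DEFAULT_THRESHOLD = 0.51
DEFAULT_QUAD_SEGS = 64  # vertices per quarter circle; area error ~1e-4 %


def buffer_provider(point: Point, radius_miles: float = DEFAULT_RADIUS_MILES,
                    quad_segs: int = DEFAULT_QUAD_SEGS) -> shapely.Polygon:
    """Circular buffer around a planar provider point, radius in miles.

    The buffer is never clipped at construction; clipping to the study
    region happens only where an analysis requires it.
    """
    if radius_miles <= 0:
        raise ValueError(f"buffer radius must be positive, got {radius_miles}")
    return point.buffer(radius_miles, quad_segs=quad_segs)


def tract_coverage_fraction(tract: shapely.Polygon, buf: shapely.Polygon,
                            tract_id: str | None = None) -> float:
    """Fraction of the tract's area inside the buffer (exact clipping)."""
    area = tract.area
    if area <= 0:
        raise ValueError(f"zero-area tract{f' {tract_id}' if tract_id else ''}")
    return float(tract.intersection(buf).area / area)


def served(area_fraction: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Strictly more than ``threshold`` of the tract area must be covered."""
    if not 0.0 <= area_fraction <= 1.0 + 1e-12:
        raise ValueError(f"area fraction outside [0, 1]: {area_fraction}")
    return area_fraction > threshold


def _clean(geom: shapely.Geometry, tract_id: str) -> shapely.Geometry:
    if not geom.is_valid:
        log.warning("repairing invalid geometry for tract %s", tract_id)
        geom = geom.buffer(0)
    return geom


def coverage_matrix(
    providers: pd.DataFrame,
    tracts: pd.DataFrame,
    radius_miles: float = DEFAULT_RADIUS_MILES,
    threshold: float = DEFAULT_THRESHOLD,
    quad_segs: int = DEFAULT_QUAD_SEGS,
) -> pd.DataFrame:
    """Per-(provider, tract) area fractions and served flags.

    ``providers`` needs ``provider_id``, ``x``, ``y`` (planar miles);
    ``tracts`` needs ``tract_id`` and planar ``geometry``.  The matrix is
    sparse: only pairs whose buffer and tract intersect are listed (every
    absent pair has area fraction 0 and is not served).
    """
    geoms = [_clean(g, t) for g, t in zip(tracts["geometry"], tracts["tract_id"])]
    tract_ids = tracts["tract_id"].to_list()
    tree = shapely.STRtree(geoms)
    entries: list[tuple[str, str, float, bool]] = []
    for pid, px, py in zip(providers["provider_id"], providers["x"], providers["y"]):
        buf = buffer_provider(Point(px, py), radius_miles, quad_segs=quad_segs)
        for j in sorted(tree.query(buf, predicate="intersects")):
            frac = tract_coverage_fraction(geoms[j], buf, tract_ids[j])
            if frac > 0.0:
                entries.append((pid, tract_ids[j], frac, served(frac, threshold)))
    if not entries:
        return pd.DataFrame(
            {
                "provider_id": pd.Series(dtype=str),
                "tract_id": pd.Series(dtype=str),
                "area_fraction": pd.Series(dtype=float),
                "served": pd.Series(dtype=bool),
            }
        )
    out = pd.DataFrame(entries, columns=["provider_id", "tract_id", "area_fraction", "served"])
    return out.sort_values(["provider_id", "tract_id"]).reset_index(drop=True)


def count_providers(
    coverage: pd.DataFrame,
    tracts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate served pairs to per-tract and per-county provider counts.

    Every tract appears in the output (count 0 if unserved); county
    counts are sums over member tracts.  A tract without a parent county
    id is fatal.
    """
    if tracts["county_id"].isna().any() or (tracts["county_id"] == "").any():
        orphans = tracts.loc[
            tracts["county_id"].isna() | (tracts["county_id"] == ""), "tract_id"
        ].tolist()
        raise ValueError(f"tract(s) without parent county: {orphans}")

    served_pairs = coverage[coverage["served"]]
    per_tract = served_pairs.groupby("tract_id").size()
    tract_counts = pd.DataFrame(
        {
            "unit_id": tracts["tract_id"],
            "county_id": tracts["county_id"],
            "provider_count": tracts["tract_id"].map(per_tract).fillna(0).astype(int),
        }
    ).sort_values("unit_id").reset_index(drop=True)

    county_counts = (
        tract_counts.groupby("county_id")["provider_count"]
        .sum()
        .reset_index()
        .rename(columns={"county_id": "unit_id"})
        .sort_values("unit_id")
        .reset_index(drop=True)
    )
    log.info(
        "coverage: %d served (provider,tract) pairs; %d/%d tracts served",
        len(served_pairs),
        int((tract_counts["provider_count"] > 0).sum()),
        len(tract_counts),
    )
    return tract_counts, county_counts


def count_distinct_providers(
    coverage: pd.DataFrame, tracts: pd.DataFrame
) -> pd.DataFrame:
    """Alternative county aggregation counting each provider once per
    county (deduplicated across the county's tracts).

    This deviates from the reference aggregation (sum of tract counts),
    which multiply-counts a provider serving several tracts of one
    county; see the methods note for why the summed form is the default.
    """
    served_pairs = coverage[coverage["served"]]
    merged = served_pairs.merge(
        tracts[["tract_id", "county_id"]], on="tract_id", how="left"
    )
    per_county = merged.groupby("county_id")["provider_id"].nunique()
    counties = sorted(tracts["county_id"].unique())
    return pd.DataFrame(
        {
            "unit_id": counties,
            "provider_count": [int(per_county.get(c, 0)) for c in counties],
        }
    )
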