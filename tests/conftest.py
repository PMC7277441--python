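"""Shared fixtures and independent geometric oracles.

The oracles here deliberately avoid the code paths they check: area
fractions are estimated by Monte-Carlo point sampling, distances by the
haversine formula on the sphere, and polygon areas by the spherical
shoelace formula.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
import shapely

from ldctaccess.projection import EARTH_RADIUS_MILES
from ldctaccess.synthetic import SyntheticScenario, generate_bundle


def mc_area_fraction(tract, other, n_points: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of area(tract & other) / area(tract).

    Samples points uniformly inside ``tract`` by rejection from its
    bounding box, then tests membership in ``other`` point-by-point.
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = tract.bounds
    inside_tract = 0
    inside_both = 0
    while inside_tract < n_points:
        m = max(n_points, 4 * (n_points - inside_tract))
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        in_t = shapely.contains_xy(tract, xs, ys)
        take = min(int(in_t.sum()), n_points - inside_tract)
        if take == 0:
            continue
        xs_t = xs[in_t][:take]
        ys_t = ys[in_t][:take]
        inside_tract += take
        inside_both += int(shapely.contains_xy(other, xs_t, ys_t).sum())
    return inside_both / inside_tract


def haversine_miles(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance on the authalic sphere, in miles."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_MILES * math.asin(math.sqrt(a))


def spherical_polygon_area_sqmi(lons, lats) -> float:
    """Spherical shoelace area of a lon/lat ring, in square miles."""
    lam = np.radians(np.asarray(lons, dtype=float))
    phi = np.radians(np.asarray(lats, dtype=float))
    if lam[0] != lam[-1] or phi[0] != phi[-1]:
        lam = np.append(lam, lam[0])
        phi = np.append(phi, phi[0])
    s = np.sum((lam[1:] - lam[:-1]) * (2.0 + np.sin(phi[:-1]) + np.sin(phi[1:])))
    return abs(s) * EARTH_RADIUS_MILES**2 / 2.0


@pytest.fixture(scope="session")
def small_bundle():
    """An 8x8-tract, 4-county, 20-provider synthetic study region."""
    scenario = SyntheticScenario(
        seed=7, nx=8, ny=8, tract_side_miles=10.0, county_block=4, n_providers=20
    )
    return generate_bundle(scenario)


@pytest.fixture(scope="session")
def medium_bundle():
    """A 100-tract instance with jittered tract boundaries, used by the
    geometry-oracle and monotonicity checks."""
    scenario = SyntheticScenario(
        seed=11, nx=10, ny=10, tract_side_miles=12.0, county_block=5,
        n_providers=5, vertex_jitter=0.25, n_subthreshold=3, n_decoy_rows=2,
    )
    return generate_bundle(scenario)
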