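"""Buffering, area fractions, the served rule, and count aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, Polygon, box

from ldctaccess.coverage import (
    buffer_provider,
    count_providers,
    count_distinct_providers,
    coverage_matrix,
    served,
    tract_coverage_fraction,
)
from ldctaccess.synthetic import make_grid_tracts, SyntheticScenario

from conftest import mc_area_fraction


class TestBuffer:
    def test_area_close_to_circle(self):
        buf = buffer_provider(Point(0, 0), 30.0)
        assert buf.area == pytest.approx(math.pi * 30**2, rel=1e-3)

    def test_doubling_radius_quadruples_area(self):
        a1 = buffer_provider(Point(5, 5), 15.0).area
        a2 = buffer_provider(Point(5, 5), 30.0).area
        assert a2 / a1 == pytest.approx(4.0, rel=1e-6)

    @pytest.mark.parametrize("r", [0.0, -3.0])
    def test_non_positive_radius_rejected(self, r):
        with pytest.raises(ValueError):
            buffer_provider(Point(0, 0), r)


class TestAreaFraction:
    def test_disjoint_and_contained(self):
        tract = box(0, 0, 1, 1)
        assert tract_coverage_fraction(tract, box(5, 5, 6, 6)) == 0.0
        assert tract_coverage_fraction(tract, box(-1, -1, 2, 2)) == pytest.approx(1.0, abs=1e-9)

    def test_half_plane_overlap_is_half(self):
        """A buffer whose edge bisects a unit square covers half its
        area; checked against the Monte-Carlo point-sampling oracle."""
        tract = box(0, 0, 1, 1)
        # large-radius buffer approximates a half-plane x <= 0.5
        buf = buffer_provider(Point(0.5 - 1000.0, 0.5), 1000.0, quad_segs=512)
        frac = tract_coverage_fraction(tract, buf)
        assert frac == pytest.approx(0.5, abs=1e-3)
        assert frac == pytest.approx(mc_area_fraction(tract, buf), abs=0.01)

    def test_zero_area_tract_is_error_naming_tract(self):
        degenerate = Polygon([(0, 0), (1, 0), (0, 0)])
        with pytest.raises(ValueError, match="T999"):
            tract_coverage_fraction(degenerate, box(0, 0, 1, 1), tract_id="T999")


class TestServedRule:
    @pytest.mark.parametrize(
        "frac,expect",
        [(0.51, False), (0.510001, True), (1.0, True), (0.0, False), (0.509999, False)],
    )
    def test_strict_threshold(self, frac, expect):
        assert served(frac) is expect


def _providers(*pts):
    return pd.DataFrame(
        [(f"p{i}", x, y) for i, (x, y) in enumerate(pts)],
        columns=["provider_id", "x", "y"],
    )


def _tracts(scenario=None):
    scenario = scenario or SyntheticScenario(
        seed=3, nx=4, ny=4, tract_side_miles=10.0, county_block=2
    )
    tracts, _ = make_grid_tracts(scenario)
    return tracts


class TestCounts:
    def test_two_providers_serving_one_tract(self):
        tracts = _tracts()
        cov = coverage_matrix(_providers((0, 0), (1, 1)), tracts, radius_miles=30)
        counts, _ = count_providers(cov, tracts)
        # the central tracts lie well inside both 30-mile buffers
        central = counts[counts["unit_id"] == tracts["tract_id"][5]]
        assert int(central["provider_count"].iloc[0]) == 2

    def test_county_count_is_sum_of_member_tracts_brute_force(self):
        """County counts match an independent per-(provider, tract)
        enumeration with a provider serving only part of one county."""
        tracts = _tracts()
        providers = _providers((-15, -15), (18, 3))
        cov = coverage_matrix(providers, tracts, radius_miles=12)
        tract_counts, county_counts = count_providers(cov, tracts)

        # brute force: recompute served pairs pair-by-pair
        brute = {}
        for _, prow in providers.iterrows():
            buf = buffer_provider(Point(prow["x"], prow["y"]), 12)
            for _, trow in tracts.iterrows():
                frac = tract_coverage_fraction(trow["geometry"], buf)
                if frac > 0.51:
                    brute[trow["county_id"]] = brute.get(trow["county_id"], 0) + 1
        for _, row in county_counts.iterrows():
            assert row["provider_count"] == brute.get(row["unit_id"], 0)
        # and at least one county is partially served (1 <= count < tracts/county)
        partial = county_counts[
            (county_counts["provider_count"] > 0) & (county_counts["provider_count"] < 4)
        ]
        assert len(partial) > 0

    def test_no_providers_all_counts_zero(self):
        tracts = _tracts()
        cov = coverage_matrix(_providers(), tracts)
        tract_counts, county_counts = count_providers(cov, tracts)
        assert (tract_counts["provider_count"] == 0).all()
        assert (county_counts["provider_count"] == 0).all()

    def test_orphan_tract_is_fatal(self):
        tracts = _tracts().copy()
        tracts.loc[0, "county_id"] = ""
        cov = coverage_matrix(_providers((0, 0)), tracts)
        with pytest.raises(ValueError, match="without parent county"):
            count_providers(cov, tracts)

    def test_distinct_provider_aggregation_never_exceeds_summed(self):
        tracts = _tracts()
        providers = _providers((0, 0), (5, 5), (-20, 10))
        cov = coverage_matrix(providers, tracts, radius_miles=25)
        _, summed = count_providers(cov, tracts)
        distinct = count_distinct_providers(cov, tracts)
        merged = summed.merge(distinct, on="unit_id", suffixes=("_sum", "_distinct"))
        assert (merged["provider_count_distinct"] <= merged["provider_count_sum"]).all()
        assert (merged["provider_count_distinct"] <= len(providers)).all()


class TestInvariants:
    def test_monotone_in_radius(self):
        tracts = _tracts()
        providers = _providers((0, 0), (-12, 17))
        prev_pairs: set = set()
        prev_counts = None
        for r in (10, 20, 30):
            cov = coverage_matrix(providers, tracts, radius_miles=r)
            pairs = set(map(tuple, cov[cov["served"]][["provider_id", "tract_id"]].values))
            assert prev_pairs <= pairs
            tract_counts, _ = count_providers(cov, tracts)
            if prev_counts is not None:
                assert (tract_counts["provider_count"] >= prev_counts).all()
            prev_pairs = pairs
            prev_counts = tract_counts["provider_count"]

    def test_translation_invariance(self):
        tracts = _tracts()
        providers = _providers((3, -4), (-9, 12))
        cov = coverage_matrix(providers, tracts, radius_miles=18)

        shifted_tracts = tracts.copy()
        shifted_tracts["geometry"] = [
            shapely.affinity.translate(g, xoff=123.0, yoff=-45.0)
            for g in tracts["geometry"]
        ]
        shifted_providers = providers.copy()
        shifted_providers["x"] += 123.0
        shifted_providers["y"] += -45.0
        cov2 = coverage_matrix(shifted_providers, shifted_tracts, radius_miles=18)
        pd.testing.assert_series_equal(cov["served"], cov2["served"])
        np.testing.assert_allclose(
            cov["area_fraction"], cov2["area_fraction"], atol=1e-9
        )

    def test_tract_total_equals_served_pairs(self):
        tracts = _tracts()
        providers = _providers((0, 0), (10, -10), (-25, 25))
        cov = coverage_matrix(providers, tracts, radius_miles=22)
        tract_counts, county_counts = count_providers(cov, tracts)
        n_served_pairs = int(cov["served"].sum())
        assert tract_counts["provider_count"].sum() == n_served_pairs
        assert county_counts["provider_count"].sum() == n_served_pairs
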