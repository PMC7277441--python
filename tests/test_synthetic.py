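"""Synthetic geography generator: tessellation, populations, smoking
surface, provider placement, and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from ldctaccess.synthetic import (
    SyntheticScenario,
    generate_bundle,
    make_grid_tracts,
    sample_populations,
    sample_providers,
    sample_smoking_surface,
)


def _scenario(**kw):
    base = dict(seed=5, nx=4, ny=4, tract_side_miles=10.0, county_block=2, n_providers=5)
    base.update(kw)
    return SyntheticScenario(**base)


class TestGrid:
    @pytest.mark.parametrize(
        "nx,ny,block,n_tracts,n_counties,tracts_per_county",
        [(2, 2, 2, 4, 1, 4), (8, 8, 4, 64, 4, 16)],
    )
    def test_block_arithmetic(self, nx, ny, block, n_tracts, n_counties, tracts_per_county):
        tracts, counties = make_grid_tracts(
            _scenario(nx=nx, ny=ny, county_block=block)
        )
        assert len(tracts) == n_tracts
        assert len(counties) == n_counties
        assert (tracts.groupby("county_id").size() == tracts_per_county).all()

    def test_county_area_is_sum_of_member_tracts(self):
        tracts, counties = make_grid_tracts(_scenario(nx=2, ny=2, county_block=2))
        tract_area = tracts["geometry"][0].area
        assert counties["geometry"][0].area == pytest.approx(4 * tract_area, rel=1e-9)

    @pytest.mark.parametrize("jitter", [0.0, 0.25])
    def test_partition_covers_region_exactly(self, jitter):
        sc = _scenario(nx=5, ny=3, vertex_jitter=jitter)
        tracts, counties = make_grid_tracts(sc)
        total = sum(g.area for g in tracts["geometry"])
        region_area = sc.nx * sc.ny * sc.tract_side_miles**2
        assert total == pytest.approx(region_area, rel=1e-9)
        assert sum(g.area for g in counties["geometry"]) == pytest.approx(region_area, rel=1e-9)

    @pytest.mark.parametrize("bad", [dict(nx=0), dict(ny=0), dict(tract_side_miles=-1.0),
                                     dict(county_block=0)])
    def test_invalid_dimensions_rejected(self, bad):
        with pytest.raises(ValueError):
            make_grid_tracts(_scenario(**bad))


class TestPopulations:
    def test_zero_fraction_zero_means_all_positive(self):
        sc = _scenario(zero_pop_tract_fraction=0.0)
        tracts, _ = make_grid_tracts(sc)
        tract_pop, _ = sample_populations(sc, tracts)
        assert (tract_pop["medicare_pop"] > 0).all()

    def test_exact_zero_population_count(self):
        sc = _scenario(nx=10, ny=10, zero_pop_tract_fraction=0.1)
        tracts, _ = make_grid_tracts(sc)
        tract_pop, _ = sample_populations(sc, tracts)
        assert int((tract_pop["medicare_pop"] == 0).sum()) == 10

    def test_county_ffs_is_fraction_of_tract_sum(self):
        sc = _scenario(ffs_fraction=0.7)
        tracts, _ = make_grid_tracts(sc)
        tract_pop, county_pop = sample_populations(sc, tracts)
        merged = tract_pop.merge(tracts[["tract_id", "county_id"]], on="tract_id")
        sums = merged.groupby("county_id")["medicare_pop"].sum()
        for _, row in county_pop.iterrows():
            assert row["ffs_pop"] == round(0.7 * sums[row["county_id"]])


class TestSmokingSurface:
    def test_zero_sd_gives_constant_surface(self):
        sc = _scenario(smoking_sd_pct=0.0)
        _, counties = make_grid_tracts(sc)
        smoking = sample_smoking_surface(sc, counties)
        assert (smoking["smoking_prev_pct"] == sc.smoking_mean_pct).all()

    def test_mean_calibration_at_many_counties(self):
        sc = _scenario(nx=20, ny=20, county_block=2, smoking_mean_pct=17.5)
        _, counties = make_grid_tracts(sc)  # 100 counties
        smoking = sample_smoking_surface(sc, counties)
        prev = smoking["smoking_prev_pct"]
        assert abs(prev.mean() - 17.5) < 1.0
        assert abs(prev.median() - 17.5) < 1.5
        assert prev.between(0, 100, inclusive="neither").all()

    def test_smoothing_raises_neighbor_correlation(self):
        """The kernel-smoothed surface has higher lag-1 (rook-neighbor)
        correlation than unsmoothed iid noise on the same county grid."""
        sc = _scenario(nx=20, ny=20, county_block=2)
        _, counties = make_grid_tracts(sc)
        smoking = sample_smoking_surface(sc, counties)

        side = 10  # counties per side
        vals = smoking["smoking_prev_pct"].to_numpy()
        ids = smoking["county_id"].tolist()
        grid = {(int(i[1:3]), int(i[3:5])): v for i, v in zip(ids, vals)}

        def lag1_corr(values_by_cell):
            pairs = []
            for (r, c), v in values_by_cell.items():
                for dr, dc in ((0, 1), (1, 0)):
                    nb = values_by_cell.get((r + dr, c + dc))
                    if nb is not None:
                        pairs.append((v, nb))
            a = np.array(pairs)
            return np.corrcoef(a[:, 0], a[:, 1])[0, 1]

        rng = np.random.default_rng(99)
        noise_grid = {
            (r, c): rng.normal() for r in range(side) for c in range(side)
        }
        assert lag1_corr(grid) > lag1_corr(noise_grid) + 0.3


class TestProviders:
    def test_negative_clustering_anticorrelates_with_smoking(self):
        from scipy.stats import spearmanr

        sc = _scenario(nx=12, ny=12, county_block=2, n_providers=80,
                       provider_clustering=-1.0, effect_strength=4.0,
                       n_subthreshold=0, n_decoy_rows=0)
        tracts, counties = make_grid_tracts(sc)
        smoking = sample_smoking_surface(sc, counties)
        providers = sample_providers(sc, counties, smoking)
        proj = sc.projection()
        x, y = proj.forward(providers["longitude"].to_numpy(),
                            providers["latitude"].to_numpy())
        import shapely
        counts = []
        for geom in counties["geometry"]:
            counts.append(int(shapely.contains_xy(geom, x, y).sum()))
        rho, _ = spearmanr(counts, smoking["smoking_prev_pct"])
        assert rho < 0

    def test_no_providers_gives_empty_table(self):
        sc = _scenario(n_providers=0, n_subthreshold=0, n_decoy_rows=0)
        _, counties = make_grid_tracts(sc)
        smoking = sample_smoking_surface(sc, counties)
        providers = sample_providers(sc, counties, smoking)
        assert providers.empty

    def test_retained_totals_respect_privacy_floor(self):
        bundle = generate_bundle(_scenario(n_providers=30))
        rows = bundle.providers
        screening = rows[rows["hcpcs_code"] == "G0297"]
        totals = screening.groupby("npi")["line_srvc_cnt"].sum()
        retained = totals[totals.index.str.startswith("P")]
        assert (retained >= 11).all()
        sub = totals[totals.index.str.startswith("S")]
        assert (sub < 11).all() and len(sub) == 8


class TestBundle:
    def test_same_seed_reproduces_bundle_exactly(self, tmp_path):
        from ldctaccess.synthetic import write_bundle

        sc = _scenario(vertex_jitter=0.2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(generate_bundle(sc), d1)
        write_bundle(generate_bundle(sc), d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_truth_labels_mark_high_smoking_counties(self):
        bundle = generate_bundle(
            _scenario(nx=12, ny=12, county_block=2, provider_clustering=-1.0)
        )
        truth = bundle.truth
        assert set(truth["county_id"]) == set(bundle.counties["county_id"])
        planted = truth[truth["planted_label"] == "high-smoking/low-access"]
        assert len(planted) > 0
        merged = planted.merge(bundle.smoking, on="county_id")
        background = truth.merge(bundle.smoking, on="county_id")
        thresh = background["smoking_prev_pct"].quantile(0.6)
        assert (merged["smoking_prev_pct"] > thresh).all()
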