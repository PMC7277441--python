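"""Seeded synthetic study geography.

Generates every input the accessibility pipeline consumes: a rectangular
grid of census tracts partitioned into block counties, right-skewed
tract Medicare populations with a configurable fraction of
zero-population tracts, a spatially autocorrelated county smoking
surface, and a provider utilization table whose spatial intensity is
correlated (positively or negatively) with the smoking surface.  The
table emulates the public-use file's quirks: rows below the 11-service
privacy floor, decoy procedure codes, and providers whose total is split
across multiple rows.

Planted truth: with negative provider clustering, counties in the top
smoking tertile are starved of providers and labelled
``high-smoking/low-access`` in ``truth.csv``, so recovery tests can
score the pipeline against ground truth without re-deriving it.

One global seed feeds a separate hierarchical RNG stream per
sub-generator (jitter, populations, smoking, providers, ...), so adding
or reordering one generator never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .classify import percentile_ranks, tertile_levels
from .geojson_io import write_layer
from .projection import AlbersEqualArea, unproject_layer

# RNG stream indices (hierarchical: default_rng([seed, stream]))
_S_JITTER, _S_POP, _S_SMOKE, _S_PROV, _S_SUBTHRESH, _S_DECOY = range(6)

DECOY_CODES = ("71250", "G0296")

TRUTH_MISMATCH = "high-smoking/low-access"
TRUTH_ALIGNED = "high-smoking/high-access"
TRUTH_BACKGROUND = "background"


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study region.

    Defaults describe the reference conditions: a 280 x 280 mile region
    of 7-mile square tracts grouped into 4x4-tract counties, provider
    placement moderately *anti*-correlated with smoking (the misalignment
    the analysis is designed to expose), county smoking centred at 17.5%
    (sd 3.4), and ~3% of tracts with zero Medicare beneficiaries.
    """

    seed: int = 0
    nx: int = 40
    ny: int = 40
    tract_side_miles: float = 7.0
    county_block: int = 4
    n_providers: int = 50
    provider_clustering: float = -0.6  # in [-1, 1]; sign of corr(intensity, smoking)
    zero_pop_tract_fraction: float = 0.03
    smoking_mean_pct: float = 17.5
    smoking_sd_pct: float = 3.4
    # secondary knobs
    vertex_jitter: float = 0.0  # fraction of tract side; <0.35 keeps quads simple
    pop_median: float = 350.0  # tract Medicare population, log-normal median
    pop_sigma: float = 0.8  # log-normal shape (right skew)
    ffs_fraction: float = 0.7  # county FFS pop as fraction of summed tract pop
    smoothing_bandwidth_miles: float | None = None  # default: 1.5 county widths
    effect_strength: float = 2.0  # |log-intensity| swing per smoking sd
    service_mean: float = 27.0  # per-provider service totals (min 11)
    service_sd: float = 25.0
    n_subthreshold: int = 8  # sub-11 rows exercising the ingest floor
    n_decoy_rows: int = 6  # rows with non-screening procedure codes
    split_row_fraction: float = 0.3  # providers whose total spans two rows
    truth_labels: tuple[str, ...] = (TRUTH_MISMATCH, TRUTH_ALIGNED, TRUTH_BACKGROUND)

    def validate(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError(f"grid dimensions must be >= 1, got nx={self.nx}, ny={self.ny}")
        if self.tract_side_miles <= 0:
            raise ValueError(f"tract_side_miles must be positive, got {self.tract_side_miles}")
        if self.county_block < 1:
            raise ValueError(f"county_block must be >= 1, got {self.county_block}")
        if not -1.0 <= self.provider_clustering <= 1.0:
            raise ValueError("provider_clustering must lie in [-1, 1]")
        if not 0.0 <= self.zero_pop_tract_fraction < 1.0:
            raise ValueError("zero_pop_tract_fraction must lie in [0, 1)")
        if not 0.0 <= self.vertex_jitter < 0.35:
            raise ValueError("vertex_jitter must lie in [0, 0.35)")
        if self.n_providers < 0:
            raise ValueError("n_providers must be >= 0")

    def projection(self) -> AlbersEqualArea:
        """Projection centred on the synthetic region."""
        return AlbersEqualArea()

    def bandwidth(self) -> float:
        if self.smoothing_bandwidth_miles is not None:
            return self.smoothing_bandwidth_miles
        return 1.5 * self.county_block * self.tract_side_miles


@dataclass
class SyntheticBundle:
    """In-memory counterpart of the files a scenario writes."""

    scenario: SyntheticScenario
    tracts: pd.DataFrame  # planar; tract_id, county_id, geometry
    counties: pd.DataFrame  # planar; county_id, geometry
    tract_pop: pd.DataFrame  # tract_id, medicare_pop
    county_pop: pd.DataFrame  # county_id, ffs_pop
    smoking: pd.DataFrame  # county_id, smoking_prev_pct
    providers: pd.DataFrame  # npi, hcpcs_code, line_srvc_cnt, longitude, latitude
    truth: pd.DataFrame  # county_id, planted_label


def make_grid_tracts(scenario: SyntheticScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tessellate the region into quadrilateral tracts and block counties.

    Returns planar (mile-unit) tract and county layers.  Tracts are
    rectangles whose shared interior vertices may be jittered
    (``vertex_jitter``); because jitter moves shared vertices, the
    layers remain an exact partition of the rectangular region.
    """
    scenario.validate()
    nx, ny, side = scenario.nx, scenario.ny, scenario.tract_side_miles
    xs = (np.arange(nx + 1) - nx / 2.0) * side
    ys = (np.arange(ny + 1) - ny / 2.0) * side
    vx, vy = np.meshgrid(xs, ys, indexing="xy")  # shape (ny+1, nx+1)

    if scenario.vertex_jitter > 0:
        rng = np.random.default_rng([scenario.seed, _S_JITTER])
        dx = rng.uniform(-1, 1, vx.shape) * scenario.vertex_jitter * side
        dy = rng.uniform(-1, 1, vy.shape) * scenario.vertex_jitter * side
        # boundary vertices stay fixed so the region stays an exact rectangle
        dx[0, :] = dx[-1, :] = 0.0
        dx[:, 0] = dx[:, -1] = 0.0
        dy[0, :] = dy[-1, :] = 0.0
        dy[:, 0] = dy[:, -1] = 0.0
        vx = vx + dx
        vy = vy + dy

    records = []
    for r in range(ny):
        for c in range(nx):
            county_id = f"C{r // scenario.county_block:02d}{c // scenario.county_block:02d}"
            tract_id = f"{county_id}T{r:03d}{c:03d}"
            poly = Polygon(
                [
                    (vx[r, c], vy[r, c]),
                    (vx[r, c + 1], vy[r, c + 1]),
                    (vx[r + 1, c + 1], vy[r + 1, c + 1]),
                    (vx[r + 1, c], vy[r + 1, c]),
                ]
            )
            records.append({"tract_id": tract_id, "county_id": county_id, "geometry": poly})
    tracts = pd.DataFrame.from_records(records).sort_values("tract_id").reset_index(drop=True)

    county_rows = []
    for county_id, group in tracts.groupby("county_id"):
        geom = shapely.unary_union(list(group["geometry"]))
        county_rows.append({"county_id": county_id, "geometry": geom})
    counties = pd.DataFrame.from_records(county_rows).sort_values("county_id").reset_index(drop=True)
    return tracts, counties


def sample_populations(
    scenario: SyntheticScenario, tracts: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal tract Medicare populations; exact zero-population count.

    County FFS population is ``ffs_fraction`` of its tracts' summed
    population, rounded to the nearest integer.
    """
    rng = np.random.default_rng([scenario.seed, _S_POP])
    n = len(tracts)
    pops = rng.lognormal(mean=np.log(scenario.pop_median), sigma=scenario.pop_sigma, size=n)
    pops = np.maximum(np.rint(pops).astype(int), 1)
    n_zero = int(round(scenario.zero_pop_tract_fraction * n))
    if n_zero:
        zero_idx = rng.choice(n, size=n_zero, replace=False)
        pops[zero_idx] = 0
    tract_pop = pd.DataFrame({"tract_id": tracts["tract_id"], "medicare_pop": pops})

    merged = tract_pop.merge(tracts[["tract_id", "county_id"]], on="tract_id")
    county_sum = merged.groupby("county_id")["medicare_pop"].sum()
    county_pop = pd.DataFrame(
        {
            "county_id": county_sum.index,
            "ffs_pop": np.rint(scenario.ffs_fraction * county_sum.to_numpy()).astype(int),
        }
    ).reset_index(drop=True)
    return tract_pop, county_pop


def sample_smoking_surface(
    scenario: SyntheticScenario, counties: pd.DataFrame
) -> pd.DataFrame:
    """Spatially autocorrelated county smoking prevalence (%).

    Independent Gaussian noise at county centroids is smoothed with a
    Gaussian kernel (bandwidth ~1.5 county widths by default), affinely
    rescaled to the target mean/sd, and clipped to (0.1, 99.9).
    """
    rng = np.random.default_rng([scenario.seed, _S_SMOKE])
    cents = np.array([[g.centroid.x, g.centroid.y] for g in counties["geometry"]])
    n = len(counties)
    noise = rng.normal(size=n)
    if scenario.smoking_sd_pct == 0 or n == 1:
        prev = np.full(n, scenario.smoking_mean_pct, dtype=float)
    else:
        h = scenario.bandwidth()
        d2 = ((cents[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 / (2.0 * h * h))
        smooth = w @ noise / w.sum(axis=1)
        sd = smooth.std()
        z = (smooth - smooth.mean()) / sd if sd > 0 else np.zeros(n)
        prev = scenario.smoking_mean_pct + scenario.smoking_sd_pct * z
    prev = np.clip(prev, 0.1, 99.9)
    return pd.DataFrame({"county_id": counties["county_id"], "smoking_prev_pct": prev})


def planted_truth(scenario: SyntheticScenario, smoking: pd.DataFrame) -> pd.DataFrame:
    """Per-county planted labels derived from the generated surface.

    Counties in the top smoking tertile are labelled by the access
    regime the provider intensity enforces: ``high-smoking/low-access``
    when clustering is negative, ``high-smoking/high-access`` when
    positive, ``background`` otherwise.
    """
    pct = percentile_ranks(smoking["smoking_prev_pct"].to_numpy())
    level = tertile_levels(pct)
    if scenario.provider_clustering < 0:
        high_label = TRUTH_MISMATCH
    elif scenario.provider_clustering > 0:
        high_label = TRUTH_ALIGNED
    else:
        high_label = TRUTH_BACKGROUND
    labels = np.where(level == "high", high_label, TRUTH_BACKGROUND)
    return pd.DataFrame({"county_id": smoking["county_id"], "planted_label": labels})


def _county_weights(scenario: SyntheticScenario, smoking: pd.DataFrame) -> np.ndarray:
    prev = smoking["smoking_prev_pct"].to_numpy(dtype=float)
    sd = prev.std()
    z = (prev - prev.mean()) / sd if sd > 0 else np.zeros(len(prev))
    w = np.exp(scenario.provider_clustering * scenario.effect_strength * z)
    return w / w.sum()


def _point_in(rng: np.random.Generator, geom: shapely.Geometry) -> Point:
    xmin, ymin, xmax, ymax = geom.bounds
    while True:
        p = Point(rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
        if geom.contains(p):
            return p


def _service_totals(rng: np.random.Generator, scenario: SyntheticScenario, size: int) -> np.ndarray:
    # total = 11 + NB(r, p), parameterized to hit the target mean/sd
    m = scenario.service_mean - 11.0
    v = scenario.service_sd**2
    if m <= 0 or v <= m:  # degenerate: constant totals
        return np.full(size, max(int(round(scenario.service_mean)), 11))
    p = m / v
    r = m * m / (v - m)
    return 11 + rng.negative_binomial(r, p, size=size)


def sample_providers(
    scenario: SyntheticScenario,
    counties: pd.DataFrame,
    smoking: pd.DataFrame,
    projection: AlbersEqualArea | None = None,
) -> pd.DataFrame:
    """Raw provider utilization rows (``npi,hcpcs_code,line_srvc_cnt,
    longitude,latitude``) in WGS84.

    Providers land in counties with probability proportional to
    ``exp(clustering * effect_strength * z_smoking)``; when clustering is
    at -1 (or +1) the opposite-extreme smoking tertile is excluded
    outright, making planted scenarios deterministic.  Retained totals
    are >= 11; ``n_subthreshold`` extra sub-11 rows and ``n_decoy_rows``
    rows with non-screening codes exercise the ingest filters.
    """
    scenario.validate()
    projection = projection or scenario.projection()
    rng = np.random.default_rng([scenario.seed, _S_PROV])
    w = _county_weights(scenario, smoking)

    if abs(scenario.provider_clustering) >= 1.0 and len(smoking) > 1:
        pct = percentile_ranks(smoking["smoking_prev_pct"].to_numpy())
        level = tertile_levels(pct)
        banned = "high" if scenario.provider_clustering < 0 else "low"
        w = np.where(level == banned, 0.0, w)
        if w.sum() == 0:
            w = np.ones(len(w))
        w = w / w.sum()

    geoms = list(counties["geometry"])
    rows: list[dict] = []

    def _emit(npi: str, code: str, count: int, pt_planar: Point) -> None:
        lon, lat = projection.inverse(pt_planar.x, pt_planar.y)
        rows.append(
            {
                "npi": npi,
                "hcpcs_code": code,
                "line_srvc_cnt": int(count),
                "longitude": float(lon),
                "latitude": float(lat),
            }
        )

    totals = _service_totals(rng, scenario, scenario.n_providers)
    retained_pts: list[Point] = []
    retained_ids: list[str] = []
    for i in range(scenario.n_providers):
        ci = rng.choice(len(geoms), p=w)
        pt = _point_in(rng, geoms[ci])
        npi = f"P{i:06d}"
        total = int(totals[i])
        if rng.uniform() < scenario.split_row_fraction and total >= 2:
            a = int(rng.integers(1, total))
            _emit(npi, "G0297", a, pt)
            _emit(npi, "G0297", total - a, pt)
        else:
            _emit(npi, "G0297", total, pt)
        retained_pts.append(pt)
        retained_ids.append(npi)

    sub_rng = np.random.default_rng([scenario.seed, _S_SUBTHRESH])
    for j in range(scenario.n_subthreshold):
        ci = sub_rng.choice(len(geoms), p=w)
        pt = _point_in(sub_rng, geoms[ci])
        _emit(f"S{j:06d}", "G0297", int(sub_rng.integers(1, 11)), pt)

    decoy_rng = np.random.default_rng([scenario.seed, _S_DECOY])
    if retained_ids:
        for j in range(scenario.n_decoy_rows):
            k = int(decoy_rng.integers(0, len(retained_ids)))
            code = DECOY_CODES[j % len(DECOY_CODES)]
            _emit(retained_ids[k], code, int(decoy_rng.integers(1, 200)), retained_pts[k])

    return pd.DataFrame(
        rows, columns=["npi", "hcpcs_code", "line_srvc_cnt", "longitude", "latitude"]
    )


def generate_bundle(scenario: SyntheticScenario) -> SyntheticBundle:
    """Generate all synthetic inputs for one scenario (in memory)."""
    scenario.validate()
    tracts, counties = make_grid_tracts(scenario)
    tract_pop, county_pop = sample_populations(scenario, tracts)
    smoking = sample_smoking_surface(scenario, counties)
    truth = planted_truth(scenario, smoking)
    providers = sample_providers(scenario, counties, smoking)
    return SyntheticBundle(
        scenario=scenario,
        tracts=tracts,
        counties=counties,
        tract_pop=tract_pop,
        county_pop=county_pop,
        smoking=smoking,
        providers=providers,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle's files (geometries in WGS84) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proj = bundle.scenario.projection()
    paths = {
        "tracts": outdir / "tracts.geojson",
        "counties": outdir / "counties.geojson",
        "providers": outdir / "providers.csv",
        "tract_pop": outdir / "tract_pop.csv",
        "county_pop": outdir / "county_pop.csv",
        "smoking": outdir / "smoking.csv",
        "truth": outdir / "truth.csv",
    }
    write_layer(unproject_layer(bundle.tracts, proj), paths["tracts"])
    write_layer(unproject_layer(bundle.counties, proj), paths["counties"])
    bundle.providers.to_csv(paths["providers"], index=False)
    bundle.tract_pop.to_csv(paths["tract_pop"], index=False)
    bundle.county_pop.to_csv(paths["county_pop"], index=False)
    bundle.smoking.to_csv(paths["smoking"], index=False)
    bundle.truth.to_csv(paths["truth"], index=False)
    return paths


def mismatch_scenario(seed: int, strong: bool = True) -> SyntheticScenario:
    """Preset used by planted-recovery tests: providers fully avoid the
    top smoking tertile (clustering -1), on coarse 20-mile tracts so a
    30-mile buffer cannot blanket neighbouring counties."""
    return SyntheticScenario(
        seed=seed,
        nx=12,
        ny=12,
        tract_side_miles=20.0,
        county_block=3,
        n_providers=40,
        provider_clustering=-1.0,
        effect_strength=8.0 if strong else 2.0,
        zero_pop_tract_fraction=0.0,
    )
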