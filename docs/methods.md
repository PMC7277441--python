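# Methods

## Accessibility model

Access is modelled as fixed-radius planar coverage: every provider reaches
everything within a 30-mile Euclidean disc of their practice location, and a
census tract counts as served by a provider when strictly more than 51% of
its area lies inside that disc. This is a deliberately simple catchment
model: no travel times, no capacity constraints, no distance decay. Its two
parameters — radius and area-fraction threshold — are configuration
(`buffer_radius_miles`, `area_fraction_threshold`) and every non-default run
is labelled as deviating from the reference configuration in the run report.

Counts aggregate bottom-up: a tract's count is the number of providers
serving it, and a county's count is the **sum** of its tracts' counts, so a
provider serving k tracts of one county contributes k. The alternative —
counting each provider once per county — is available
(`--distinct-providers`) but is not the default: summed counts are the only
reading consistent with observed county densities far above 100 providers
per 1000 beneficiaries in dense urban counties, which would be impossible
for deduplicated counts given realistic national provider totals. The summed
count is best understood as tract-coverage mass, not a headcount.

### Projection

Buffering and area fractions need one planar system with a known length
unit. We use a spherical Albers equal-area conic (authalic Earth radius,
planar unit = 1 statute mile), with closed-form forward and inverse
transforms; equal-area means tract area fractions are unbiased by the map.
Default standard parallels (35.5°, 39.5°) bracket a regional study area a
few hundred miles tall, keeping length distortion inside the region below
about 0.1% (the meridian-distance test bounds it at ±0.1 mile on a 30-mile
segment); for a continent-scale region the parallels should be widened
(e.g. 29.5°/45.5°), at the cost of up to ~1% length distortion mid-way
between them. Geometries outside a configurable validity window trigger
warnings naming the unit. Invalid (self-intersecting) tract rings are
repaired by zero-buffering with a logged warning.

### Density and summaries

Unit density is `per_capita * count / population` (default per 1000).
Zero-population units have undefined density and are excluded from every
distributional summary, mirroring the source data's exclusion of
zero-beneficiary tracts. County-level summaries *include* no-service
counties at density 0 — a summary over "all counties" that silently dropped
nearly half of them would mislead — while maps and density rankings treat
them as missing: a bottom-k density ranking of zeros carries no information,
so rankings by density cover served counties only, and smoking-ranked tables
print "not available" in the density column. Quartiles are linear
interpolation between order statistics (numpy's default); the convention is
stated here because alternatives shift IQR endpoints on small n.

### Bivariate classification

Percentiles are mid-rank: `100·(#{x<v} + ½·#{x=v})/n`. Mid-rank is
symmetric (the percentile of the middle of 9 distinct values is exactly 50),
stable under ties, and makes class balance derivable exactly; an empirical
CDF alternative (`#{x≤v}/n`) is exposed as `percentile_method=ecdf`. Levels
cut at the 34th and 67th percentiles: low `p<34`, medium `34≤p<67`, high
`p≥67`. Note these breaks are *not* exact thirds — the widths are 34/33/33,
so n distinct values split as closely as those widths allow (340/330/330 at
n=1000), not always within one of each other.

No-service counties are excluded from the density percentile pool by
default: with a large no-service share, pooling their zeros would collapse
the low and medium density tertiles onto zero and make "low density" mean
"no data". The pooled behaviour is available
(`density_pool_includes_no_service=True`) for sensitivity analysis. Whether
to pool is the one genuinely open design choice in the classification; both
behaviours are tested.

## Synthetic geography

The generator emulates the statistical shape of the real inputs, not their
geography:

- **Tracts/counties** — an nx×ny grid of square tracts (default 40×40 at
  7 miles, roughly the national mean tract area) grouped into
  county_block² blocks (default 4×4). Optional shared-vertex jitter bends
  tract boundaries while preserving the exact partition, so area-fraction
  code faces non-rectangular geometry with analytically known total area.
- **Populations** — log-normal tract Medicare populations (median 350,
  σ=0.8), matching the right skew of real small-area counts; a configurable
  fraction (default 3%) is set to exactly zero to exercise the exclusion
  path. County fee-for-service population is 70% of the summed tract
  population, the approximate national FFS share.
- **Smoking surface** — iid Gaussian noise at county centroids smoothed by a
  Gaussian kernel (bandwidth 1.5 county widths), affinely rescaled to mean
  17.5% and sd 3.4% (sd chosen so the IQR spans roughly 15–20%), clipped to
  (0.1, 99.9). This yields the spatial autocorrelation real prevalence
  surfaces show, verified by a neighbour-correlation test.
- **Providers** — county intensities `∝ exp(clustering · strength ·
  z_smoking)`; the default clustering of −0.6 encodes the misalignment
  between capacity and need that motivates the analysis. At clustering ±1
  the opposite-extreme smoking tertile is excluded outright, which is what
  planted-truth scenarios use. Service totals are 11 + negative-binomial,
  parameterized to mean 27/sd 25; sub-floor rows (counts 1–10), decoy
  procedure codes, and split-row providers exercise every ingest filter.
- **Planted truth** — with negative clustering, top-smoking-tertile counties
  are labelled `high-smoking/low-access` in `truth.csv`; recovery tests
  require ≥90% of them to come out of the pipeline as `low-high` or
  no-service-with-high-smoking.

One integer seed drives a separate `default_rng([seed, stream])` per
sub-generator, so outputs are byte-reproducible and adding a generator never
perturbs the others.

What the generator does **not** emulate: real road networks and travel
times, urban/rural population gradients, coastline and irregular county
shapes, multi-site providers, and any correlation between population size
and smoking. Passing tests therefore demonstrate correctness of the
*method* — geometry, counting, classification, reproducibility — on data
with the right statistical shape, not calibration to any real region's
numbers.

## Numerical choices

- Buffer circles are polygonized at 64 segments per quarter-circle: area
  error ~1e-4%, negligible against the 51% decision margin; the resolution
  is configurable so oracle tests can vary it.
- The served rule is strict (`fraction > 0.51`), so a tract exactly at the
  threshold is not served.
- Area fractions come from exact polygon clipping; a Monte-Carlo
  point-in-polygon oracle (10⁵ points per pair, ±0.01) cross-checks every
  overlapping pair on a 100-tract jittered instance.
- Aggregations sort by unit id and break ranking ties by id, making every
  output file deterministic byte-for-byte for a given config and seed.
- Degenerate inputs fail loudly: zero-area tracts, tracts without a parent
  county, conflicting coordinates for one provider id, and negative
  populations are all fatal rather than silently repaired, because each can
  move a unit across a served/tertile boundary.

## Problem sizes

The reference synthetic region is 1600 tracts / 100 counties / 50 providers;
recovery scenarios are 144 tracts / 16 counties / 40 providers over five
seeds. These sizes give every distributional summary at least ~70 effective
units while keeping a full pipeline run around a second, and they are the
sizes the analysis scripts and acceptance script use.

## Limitations

A fixed 30-mile disc understates rural catchments and ignores congestion;
the denominator is the Medicare FFS population, not the screening-eligible
population (30 pack-year history, age window), so densities are not uptake
rates; and the tertile labels are relative to the study region — a "high
density" county in an under-served region may still be poorly served in
absolute terms. The percentile convention and zero-pooling behaviour
measurably shift class boundaries on small n; both are configurable and
documented above rather than asserted as the only defensible choice.
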