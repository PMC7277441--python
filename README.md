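# ldctaccess

Spatial accessibility of lung-cancer-screening providers, for health-services
researchers and cancer-control planners. Low-dose CT (LDCT) screening is only
useful where a provider is reachable; this package quantifies, at census-tract
and county resolution, where LDCT capacity sits relative to the population
that needs it most — counties with high smoking prevalence.

## Method

Given a provider utilization table (one row per provider × procedure code,
with coordinates), areal units, population denominators, and a county smoking
surface, the pipeline:

1. **Ingest** — keep rows with the screening procedure code (HCPCS `G0297`),
   sum services per provider id (NPI), and drop providers with fewer than 11
   total services, the public-use file's privacy floor.
2. **Coverage** — project everything to an equal-area conic plane scaled in
   miles, draw a 30-mile buffer *B_p* around each provider *p*, and mark
   tract *t* as *served* by *p* when

   `area(t ∩ B_p) / area(t) > 0.51` (strict).

   Tract provider count = number of providers serving it; county count =
   sum over member tracts (a provider serving k tracts of a county
   contributes k).
3. **Density** — providers per 1000 beneficiaries,
   `d_u = 1000 · c_u / pop_u`, with zero-population units excluded from all
   distributional summaries.
4. **Classify** — each county's density and smoking prevalence are converted
   to mid-rank percentiles and cut into **low** (< 34th), **medium**
   (34th–67th) and **high** (≥ 67th) levels; the pair gives one of nine
   bivariate classes (density level first), and counties with no service form
   a separate `no_service` class shown as missing on maps.
5. **Report** — class-coded GeoJSON map layer, scatter CSV, top/bottom-10
   rank tables, and a run report echoing the full configuration.

Because the real inputs (Medicare utilization files, census shapefiles,
small-area smoking estimates) need bulk downloads and geocoding, the package
ships a seeded synthetic-geography generator that emulates all of them —
including sub-floor provider rows, decoy procedure codes, zero-population
tracts, a spatially autocorrelated smoking surface, and planted
"high-smoking/low-access" counties for recovery testing.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic region (1600 seven-mile tracts, 100 counties, 50 providers placed
with intensity anti-correlated with smoking, seed 1):

```sh
python analysis/01_simulate.py
python analysis/02_ingest.py
...
python analysis/06_report.py
```

`02_ingest.py` prints:

```
Retained 50 screening providers (1339 total services).
Services per provider: mean 26.8 +/- 19.8, median 20, range 11-110.
```

`04_density.py`:

```
45.5% of tracts (728/1600) have no provider serving them.
28.0% of counties (28/100) have no screening service at all.
County density: median 2.46 per 1000 (IQR 0.00-7.65) over all 100 counties;
restricted to the 72 served counties, median 4.59 (IQR 2.16-9.64).
```

and `05_classify.py`:

```
density_level  low  medium  high
          low    5      10     9
       medium    7      14     3
         high   22       2     0
   no_service    0       7    21
```

Read the crosstab column-wise: of the high-smoking counties, none is
high-density and 21 have no service at all, while 22 of the 24 high-density
counties sit in low-smoking areas — the access/need misalignment the
bivariate map is designed to expose. All stage outputs land in `results/run/`.

The same pipeline runs from a shell on any conforming inputs:

```sh
ldct-access all --seed 1 --outdir results/run      # simulate + analyze
ldct-access coverage --indir data/ --outdir out/   # one stage, real inputs
```

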