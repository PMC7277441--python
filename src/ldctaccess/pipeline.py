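"""Stage orchestration: simulate -> ingest -> coverage -> density ->
classify -> report.

Each stage reads the previous stage's persisted files and writes its
own, so any stage can be re-run from intermediates.  All outputs are
deterministic given identical inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import coverage as _coverage
from . import density as _density
from . import ingest as _ingest
from . import report as _report
from . import synthetic as _synthetic
from .config import RunConfig
from .geojson_io import read_layer
from .projection import AlbersEqualArea, project_layer

log = logging.getLogger("ldctaccess.pipeline")

STAGE_ORDER = ("ingest", "coverage", "density", "classify", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


def _projection(cfg: RunConfig) -> AlbersEqualArea:
    if cfg.projection != "albers_equal_area":
        raise ValueError(f"unknown projection id: {cfg.projection!r}")
    return AlbersEqualArea()


def _scenario_from_config(cfg: RunConfig) -> _synthetic.SyntheticScenario:
    if cfg.seed is None:
        raise ValueError("simulate requires a seed")
    kwargs: dict = {"seed": cfg.seed}
    valid = {f.name: f.type for f in dataclasses.fields(_synthetic.SyntheticScenario)}
    for key, value in cfg.scenario_overrides.items():
        if key not in valid:
            raise ValueError(f"unknown scenario field: {key!r}")
        current = getattr(_synthetic.SyntheticScenario(), key)
        if isinstance(current, bool):
            value = str(value).lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            value = int(value)
        elif isinstance(current, float):
            value = float(value)
        kwargs[key] = value
    return _synthetic.SyntheticScenario(**kwargs)


def stage_simulate(cfg: RunConfig) -> dict[str, Path]:
    scenario = _scenario_from_config(cfg)
    bundle = _synthetic.generate_bundle(scenario)
    paths = _synthetic.write_bundle(bundle, cfg.outdir)
    log.info(
        "simulate: %d tracts, %d counties, %d provider rows, seed=%d",
        len(bundle.tracts), len(bundle.counties), len(bundle.providers), scenario.seed,
    )
    return paths


def stage_ingest(cfg: RunConfig) -> pd.DataFrame:
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        result = _ingest.load_provider_table(indir / "providers.csv")
    except (OSError, _ingest.SchemaError) as exc:
        raise StageError("provider_ingest", str(exc)) from exc
    for err in result.errors:
        log.warning("ingest: line %d rejected: %s", err.line, err.message)
    n_raw = len(result.rows)
    records = _ingest.filter_and_aggregate(
        result.rows, code=cfg.procedure_code, min_services=cfg.min_services
    )
    n_code = int((result.rows["hcpcs_code"] == cfg.procedure_code).sum())
    log.info(
        "ingest: rows_in=%d rows_matching_code=%d providers_retained=%d "
        "dropped_below_floor=%d",
        n_raw, n_code,
        len(records),
        result.rows[result.rows["hcpcs_code"] == cfg.procedure_code]["npi"].nunique()
        - len(records),
    )
    records.to_csv(outdir / "providers_clean.csv", index=False)
    summary = _ingest.provider_summary(records)
    (outdir / "provider_summary.json").write_text(summary.to_json())
    return records


def stage_coverage(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    proj = _projection(cfg)
    try:
        providers = pd.read_csv(outdir / "providers_clean.csv", dtype={"provider_id": str})
        tracts = read_layer(indir / "tracts.geojson")
    except OSError as exc:
        raise StageError("coverage_model", str(exc)) from exc
    tracts_planar = project_layer(tracts, proj, id_column="tract_id")
    if len(providers):
        x, y = proj.forward(providers["lon"].to_numpy(), providers["lat"].to_numpy())
    else:
        x, y = [], []
    providers_planar = providers.assign(x=x, y=y)
    cov = _coverage.coverage_matrix(
        providers_planar,
        tracts_planar,
        radius_miles=cfg.buffer_radius_miles,
        threshold=cfg.area_fraction_threshold,
    )
    tract_counts, county_counts = _coverage.count_providers(cov, tracts_planar)
    if cfg.distinct_providers:
        log.warning("coverage: distinct-provider county aggregation enabled "
                    "(deviates from reference configuration)")
        county_counts = _coverage.count_distinct_providers(cov, tracts_planar)
    cov.to_csv(outdir / "coverage.csv", index=False)
    tract_counts.to_csv(outdir / "tract_counts.csv", index=False)
    county_counts.to_csv(outdir / "county_counts.csv", index=False)
    return cov, tract_counts, county_counts


def stage_density(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    try:
        tract_counts = pd.read_csv(outdir / "tract_counts.csv")
        county_counts = pd.read_csv(outdir / "county_counts.csv")
        tract_pop = pd.read_csv(indir / "tract_pop.csv")
        county_pop = pd.read_csv(indir / "county_pop.csv")
        smoking = pd.read_csv(indir / "smoking.csv")
    except OSError as exc:
        raise StageError("density_metrics", str(exc)) from exc
    dens_tract = _density.compute_density(
        tract_counts[["unit_id", "provider_count"]], tract_pop, per=cfg.per_capita
    )
    dens_county = _density.compute_density(county_counts, county_pop, per=cfg.per_capita)
    dens_tract.to_csv(outdir / "density_tract.csv", index=False)
    dens_county.to_csv(outdir / "density_county.csv", index=False)

    def _summ(s: _density.DensitySummary) -> dict:
        return {"n": s.n, "median": s.median, "q1": s.q1, "q3": s.q3}

    m_t, n_t, frac_t = _density.uncovered_fraction(dens_tract)
    m_c, n_c, frac_c = _density.uncovered_fraction(dens_county)
    summary = {
        "county_all": _summ(_density.summarize(dens_county, include_zero_density=True)),
        "county_served": _summ(_density.summarize(dens_county, include_zero_density=False)),
        "tract_all": _summ(_density.summarize(dens_tract, include_zero_density=True)),
        "tracts_uncovered": {"m": m_t, "n": n_t, "fraction": frac_t},
        "counties_no_service": {"m": m_c, "n": n_c, "fraction": frac_c},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))

    tables = []
    for by in ("density", "smoking"):
        for direction in ("top", "bottom"):
            t = _density.rank_table(dens_county, smoking, by=by, direction=direction,
                                    k=min(10, len(dens_county)))
            t.insert(0, "direction", direction)
            t.insert(0, "ranked_by", by)
            tables.append(t)
    pd.concat(tables, ignore_index=True).to_csv(outdir / "rank_tables.csv", index=False)
    return dens_tract, dens_county


def stage_classify(cfg: RunConfig) -> pd.DataFrame:
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    try:
        dens_county = pd.read_csv(outdir / "density_county.csv")
        smoking = pd.read_csv(indir / "smoking.csv")
    except OSError as exc:
        raise StageError("bivariate_classify", str(exc)) from exc
    classes = _classify.classify_bivariate(
        dens_county, smoking,
        breaks=cfg.tertile_breaks,
        percentile_method=cfg.percentile_method,
    )
    classes.to_csv(outdir / "bivariate_classes.csv", index=False)
    _classify.crosstab(classes).to_csv(outdir / "crosstab.csv", index=False)
    return classes


def stage_report(cfg: RunConfig) -> Path:
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    try:
        counties = read_layer(indir / "counties.geojson")
        dens_county = pd.read_csv(outdir / "density_county.csv")
        classes = pd.read_csv(outdir / "bivariate_classes.csv")
        smoking = pd.read_csv(indir / "smoking.csv")
        summary = json.loads((outdir / "summary.json").read_text())
        prov_summary = json.loads((outdir / "provider_summary.json").read_text())
    except OSError as exc:
        raise StageError("report_outputs", str(exc)) from exc
    layer = _report.export_map_layer(
        counties, dens_county, classes, smoking, outdir / "map_layer.geojson"
    )
    _report.export_scatter(classes, dens_county, smoking, outdir / "scatter.csv")
    if cfg.render:
        _report.render_maps(layer, outdir)
    report_path = outdir / "report.md"
    report_path.write_text(_run_report(cfg, indir, summary, prov_summary, classes))
    return report_path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _run_report(cfg: RunConfig, indir: Path, summary: dict, prov: dict,
                classes: pd.DataFrame) -> str:
    lines = ["# Run report", "", "## Configuration", ""]
    for key, value in sorted(cfg.to_dict().items()):
        lines.append(f"- {key} = {value}")
    dev = cfg.deviations()
    if dev:
        lines += ["", f"**Deviates from reference configuration:** {', '.join(dev)}"]
    lines += ["", "## Input digests (sha256/16)", ""]
    for name in ("providers.csv", "tracts.geojson", "counties.geojson",
                 "tract_pop.csv", "county_pop.csv", "smoking.csv"):
        p = indir / name
        if p.exists():
            lines.append(f"- {name}: {_digest(p)}")
    lines += ["", "## Headline statistics", ""]
    lines.append(f"- providers retained: {prov['n_providers']} "
                 f"(total services {prov['total_services']})")
    if prov["n_providers"]:
        lines.append(
            f"- services per provider: mean {prov['mean']:.1f} +/- {prov['sd']:.1f}, "
            f"median {prov['median']:.0f}, range {prov['min']}-{prov['max']}"
        )
    tu = summary["tracts_uncovered"]
    cu = summary["counties_no_service"]
    lines.append(f"- tracts without a serving provider: {tu['m']}/{tu['n']} "
                 f"({100 * tu['fraction']:.1f}%)")
    lines.append(f"- counties without service: {cu['m']}/{cu['n']} "
                 f"({100 * cu['fraction']:.1f}%)")
    ca = summary["county_all"]
    cs = summary["county_served"]
    if ca["n"]:
        lines.append(f"- county density median {ca['median']:.2f} "
                     f"(IQR {ca['q1']:.2f}-{ca['q3']:.2f}), n={ca['n']}")
    if cs["n"]:
        lines.append(f"- served-county density median {cs['median']:.2f} "
                     f"(IQR {cs['q1']:.2f}-{cs['q3']:.2f}), n={cs['n']}")
    counts = classes["code"].value_counts()
    lines += ["", "## Bivariate class counts", ""]
    for code in sorted(counts.index):
        lines.append(f"- {code}: {int(counts[code])}")
    return "\n".join(lines) + "\n"


def analyze_bundle(bundle: _synthetic.SyntheticBundle, cfg: RunConfig | None = None) -> dict:
    """Run the whole analysis in memory on a synthetic bundle.

    Returns a dict of frames/objects: ``providers`` (clean records),
    ``provider_summary``, ``coverage``, ``tract_counts``,
    ``county_counts``, ``density_tract``, ``density_county``,
    ``classes``, ``crosstab``.
    """
    cfg = cfg or RunConfig()
    cfg.validate()
    proj = bundle.scenario.projection()
    records = _ingest.filter_and_aggregate(
        bundle.providers, code=cfg.procedure_code, min_services=cfg.min_services
    )
    if len(records):
        x, y = proj.forward(records["lon"].to_numpy(), records["lat"].to_numpy())
    else:
        x, y = [], []
    cov = _coverage.coverage_matrix(
        records.assign(x=x, y=y),
        bundle.tracts,
        radius_miles=cfg.buffer_radius_miles,
        threshold=cfg.area_fraction_threshold,
    )
    tract_counts, county_counts = _coverage.count_providers(cov, bundle.tracts)
    dens_tract = _density.compute_density(
        tract_counts[["unit_id", "provider_count"]], bundle.tract_pop, per=cfg.per_capita
    )
    dens_county = _density.compute_density(county_counts, bundle.county_pop, per=cfg.per_capita)
    classes = _classify.classify_bivariate(
        dens_county, bundle.smoking,
        breaks=cfg.tertile_breaks, percentile_method=cfg.percentile_method,
    )
    return {
        "providers": records,
        "provider_summary": _ingest.provider_summary(records),
        "coverage": cov,
        "tract_counts": tract_counts,
        "county_counts": county_counts,
        "density_tract": dens_tract,
        "density_county": dens_county,
        "classes": classes,
        "crosstab": _classify.crosstab(classes),
    }


def run_pipeline(cfg: RunConfig) -> None:
    """Run ingest through report in order."""
    cfg.validate()
    stage_ingest(cfg)
    stage_coverage(cfg)
    stage_density(cfg)
    stage_classify(cfg)
    stage_report(cfg)


def run_all(cfg: RunConfig) -> None:
    """Simulate a synthetic bundle into outdir, then run the pipeline on it."""
    cfg.validate()
    stage_simulate(cfg)
    cfg_inputs = dataclasses.replace(cfg, indir=cfg.outdir)
    run_pipeline(cfg_inputs)
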