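"""Class-coded map layers, scatter data, and optional static maps.

The acceptance surface is the attribute data (GeoJSON properties and
CSV rows); rendered images are best-effort convenience output, since
cartographic styling carries no methodological content.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import LEVELS, NO_SERVICE
from .geojson_io import write_layer

log = logging.getLogger(__name__)

# 3x3 bivariate palette (density level x smoking level), corner-configurable.
DEFAULT_PALETTE = {
    ("low", "low"): "#e8e8e8",
    ("low", "medium"): "#ace4e4",
    ("low", "high"): "#5ac8c8",
    ("medium", "low"): "#dfb0d6",
    ("medium", "medium"): "#a5add3",
    ("medium", "high"): "#5698b9",
    ("high", "low"): "#be64ac",
    ("high", "medium"): "#8c62aa",
    ("high", "high"): "#3b4994",
}
NO_SERVICE_COLOR = "#ffffff"


def export_map_layer(
    counties: pd.DataFrame,
    density: pd.DataFrame,
    classes: pd.DataFrame,
    smoking: pd.DataFrame,
    path: str | Path,
) -> pd.DataFrame:
    """Join county geometries with densities, classes, and smoking, and
    write one GeoJSON layer.

    Every feature carries the full attribute set; no-service counties
    are flagged by the explicit ``no_service`` string in the level/code
    fields, never by an absent field.  Id mismatches between the layers
    are fatal.
    """
    dens = density.rename(columns={"unit_id": "county_id"})
    ids_geom = set(counties["county_id"])
    for name, ids in (
        ("density", set(dens["county_id"])),
        ("classes", set(classes["county_id"])),
        ("smoking", set(smoking["county_id"])),
    ):
        if ids != ids_geom:
            missing = sorted(ids_geom - ids)
            extra = sorted(ids - ids_geom)
            raise ValueError(
                f"county id mismatch with {name} table: "
                f"missing={missing[:5]} extra={extra[:5]}"
            )

    layer = (
        counties.merge(dens[["county_id", "density_per_1000"]], on="county_id")
        .merge(smoking, on="county_id")
        .merge(classes, on="county_id")
        .sort_values("county_id")
        .reset_index(drop=True)
    )
    # NaN density (zero-population county) -> null in JSON, field present
    layer["density_per_1000"] = [
        None if (isinstance(v, float) and np.isnan(v)) else float(v)
        for v in layer["density_per_1000"]
    ]
    layer = layer[
        ["county_id", "density_per_1000", "smoking_prev_pct",
         "density_level", "smoking_level", "code", "geometry"]
    ]
    write_layer(layer, path)
    return layer


def export_scatter(
    classes: pd.DataFrame,
    density: pd.DataFrame,
    smoking: pd.DataFrame,
    path: str | Path,
) -> pd.DataFrame:
    """CSV of (density, smoking, code) for served counties.

    No-service counties are omitted from the rows but counted in a
    header comment line.
    """
    dens = density.rename(columns={"unit_id": "county_id"})
    merged = classes.merge(dens[["county_id", "density_per_1000"]], on="county_id").merge(
        smoking, on="county_id"
    )
    served_rows = merged[merged["code"] != NO_SERVICE].sort_values("county_id")
    n_omitted = int((merged["code"] == NO_SERVICE).sum())
    out = served_rows[["county_id", "density_per_1000", "smoking_prev_pct", "code"]]
    with open(path, "w") as fh:
        fh.write(f"# no_service_counties_omitted={n_omitted}\n")
        out.to_csv(fh, index=False)
    return out.reset_index(drop=True)


def class_colors(palette: dict | None = None) -> dict[str, str]:
    palette = palette or DEFAULT_PALETTE
    colors = {f"{d}-{s}": palette[(d, s)] for d in LEVELS for s in LEVELS}
    colors[NO_SERVICE] = NO_SERVICE_COLOR
    return colors


def render_maps(layer: pd.DataFrame, outdir: str | Path, palette: dict | None = None) -> list[Path]:
    """Best-effort static choropleths (univariate density/smoking plus
    the 3x3 bivariate map).  Never fatal: a missing rendering backend
    logs a warning and returns an empty list."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.patches import Polygon as MplPolygon
        from matplotlib.collections import PatchCollection
    except Exception as exc:  # pragma: no cover - backend availability
        log.warning("map rendering skipped: %s", exc)
        return []

    colors = class_colors(palette)
    written: list[Path] = []

    def _patches(ax, values_to_color):
        patches, cols = [], []
        for _, row in layer.iterrows():
            geom = row["geometry"]
            polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
            col = values_to_color(row)
            for p in polys:
                patches.append(MplPolygon(np.asarray(p.exterior.coords)))
                cols.append(col)
        pc = PatchCollection(patches, facecolor=cols, edgecolor="0.6", linewidth=0.3)
        ax.add_collection(pc)
        ax.autoscale_view()
        ax.set_aspect("equal")
        ax.set_axis_off()

    # bivariate map
    fig, ax = plt.subplots(figsize=(8, 8))
    _patches(ax, lambda row: colors[row["code"]])
    ax.set_title("Provider density x smoking prevalence (bivariate tertiles)")
    p = outdir / "bivariate_map.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # univariate maps via sequential shading
    for var, fname, title in (
        ("density_per_1000", "density_map.png", "Provider density per 1000 beneficiaries"),
        ("smoking_prev_pct", "smoking_map.png", "Current daily smoking prevalence (%)"),
    ):
        vals = pd.to_numeric(layer[var], errors="coerce")
        vmax = np.nanmax(vals.to_numpy()) if np.isfinite(vals).any() else 1.0
        cmap = plt.get_cmap("viridis")

        def shade(row, var=var, vmax=vmax, cmap=cmap):
            v = row[var]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return NO_SERVICE_COLOR
            if var == "density_per_1000" and row["code"] == NO_SERVICE:
                return NO_SERVICE_COLOR
            return cmap(float(v) / vmax if vmax > 0 else 0.0)

        fig, ax = plt.subplots(figsize=(8, 8))
        _patches(ax, shade)
        ax.set_title(title)
        p = outdir / fname
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
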