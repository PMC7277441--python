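"""Tertile-based bivariate classification of counties.

Each county gets a low/medium/high level on provider density and on
smoking prevalence by percentile-cutting each variable at the 34th and
67th percentiles, and the two levels combine into one of nine bivariate
codes (density level first, e.g. ``low-high`` = low density, high
smoking).  Counties without any provider service form a distinct
``no_service`` class: they are excluded from the density percentile pool
(they are missing on the maps, not "low") but keep their smoking level.

Percentiles use the mid-rank convention,
``100 * (#{x < v} + 0.5 * #{x == v}) / n``, which is symmetric and
tie-stable; an empirical-CDF alternative (``#{x <= v} / n``) is
available via ``method="ecdf"``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

LEVELS = ("low", "medium", "high")
NO_SERVICE = "no_service"
DEFAULT_BREAKS = (34.0, 67.0)


def percentile_rank(values, v, method: str = "midrank") -> float:
    """Percentile (0-100) of ``v`` within ``values``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile_rank: empty value pool")
    if method == "midrank":
        below = np.count_nonzero(values < v)
        ties = np.count_nonzero(values == v)
        return 100.0 * (below + 0.5 * ties) / values.size
    if method == "ecdf":
        return 100.0 * np.count_nonzero(values <= v) / values.size
    raise ValueError(f"unknown percentile method: {method!r}")


def percentile_ranks(values, method: str = "midrank") -> np.ndarray:
    """Percentile of every element within its own pool (vectorized)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile_ranks: empty value pool")
    order = np.argsort(values, kind="mergesort")
    sorted_v = values[order]
    # For each v: #{x < v} via left insertion, ties via right - left.
    left = np.searchsorted(sorted_v, values, side="left")
    right = np.searchsorted(sorted_v, values, side="right")
    if method == "midrank":
        pct = 100.0 * (left + 0.5 * (right - left)) / values.size
    elif method == "ecdf":
        pct = 100.0 * right / values.size
    else:
        raise ValueError(f"unknown percentile method: {method!r}")
    return pct


def tertile_level(percentile: float, breaks: tuple[float, float] = DEFAULT_BREAKS) -> str:
    """Map a percentile to low (< breaks[0]), medium, or high (>= breaks[1])."""
    lo, hi = breaks
    if percentile < lo:
        return "low"
    if percentile < hi:
        return "medium"
    return "high"


def tertile_levels(percentiles, breaks: tuple[float, float] = DEFAULT_BREAKS) -> np.ndarray:
    p = np.asarray(percentiles, dtype=float)
    lo, hi = breaks
    out = np.where(p < lo, "low", np.where(p < hi, "medium", "high"))
    return out


def classify_bivariate(
    density: pd.DataFrame,
    smoking: pd.DataFrame,
    breaks: tuple[float, float] = DEFAULT_BREAKS,
    percentile_method: str = "midrank",
    density_pool_includes_no_service: bool = False,
) -> pd.DataFrame:
    """Assign each county its bivariate class.

    Parameters
    ----------
    density
        Per-county density records with columns ``unit_id``,
        ``density_per_1000``, ``has_service`` (from
        :func:`ldctaccess.density.compute_density`).
    smoking
        Columns ``county_id``, ``smoking_prev_pct``.
    density_pool_includes_no_service
        If True, no-service counties' zero densities stay in the density
        percentile pool (they still receive the ``no_service`` code
        themselves).  Default False: the pool holds served counties only.

    Returns
    -------
    DataFrame with ``county_id``, ``density_level``, ``smoking_level``,
    ``code`` sorted by county id.
    """
    dens = density.rename(columns={"unit_id": "county_id"})
    merged = dens.merge(smoking, on="county_id", how="left", validate="1:1")
    missing = merged[merged["smoking_prev_pct"].isna()]["county_id"].tolist()
    if missing:
        warnings.warn(
            f"{len(missing)} counties missing smoking prevalence, excluded: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
        merged = merged[merged["smoking_prev_pct"].notna()]
    merged = merged.sort_values("county_id").reset_index(drop=True)

    has = merged["has_service"].to_numpy(dtype=bool)
    dens_vals = merged["density_per_1000"].to_numpy(dtype=float)
    pool_mask = np.ones(len(merged), dtype=bool) if density_pool_includes_no_service else has
    pool = dens_vals[pool_mask]

    density_level = np.full(len(merged), NO_SERVICE, dtype=object)
    if pool.size:
        served_idx = np.flatnonzero(has)
        for i in served_idx:
            p = percentile_rank(pool, dens_vals[i], method=percentile_method)
            density_level[i] = tertile_level(p, breaks)

    smoke_pct = percentile_ranks(merged["smoking_prev_pct"].to_numpy(), method=percentile_method)
    smoking_level = tertile_levels(smoke_pct, breaks)

    code = np.where(
        density_level == NO_SERVICE,
        NO_SERVICE,
        np.char.add(np.char.add(density_level.astype(str), "-"), smoking_level),
    )
    return pd.DataFrame(
        {
            "county_id": merged["county_id"],
            "density_level": density_level,
            "smoking_level": smoking_level,
            "code": code,
        }
    )


def crosstab(classes: pd.DataFrame) -> pd.DataFrame:
    """3x3 contingency counts of (density level x smoking level) plus a
    ``no_service`` row; cell sum + no_service equals classified counties."""
    rows = []
    for d in LEVELS:
        row = {"density_level": d}
        for s in LEVELS:
            row[s] = int(((classes["density_level"] == d) & (classes["smoking_level"] == s)).sum())
        rows.append(row)
    ns_row = {"density_level": NO_SERVICE}
    ns_mask = classes["density_level"] == NO_SERVICE
    for s in LEVELS:
        ns_row[s] = int((ns_mask & (classes["smoking_level"] == s)).sum())
    rows.append(ns_row)
    return pd.DataFrame(rows)
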