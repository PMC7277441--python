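"""Per-capita provider densities and distributional summaries.

Density is providers per 1000 beneficiaries of the areal unit.  Units
with zero population have no defined density and are excluded from
distributional summaries (mirroring the exclusion of zero-beneficiary
tracts in the source data).  Summaries over counties include no-service
counties at density 0 by default; rankings by density exclude them
(their density carries no information about capacity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

NOT_AVAILABLE = "not available"


@dataclass
class DensitySummary:
    n: int
    median: float | None
    q1: float | None
    q3: float | None

    @property
    def defined(self) -> bool:
        return self.n > 0


def compute_density(
    counts: pd.DataFrame, populations: pd.DataFrame, per: int = 1000
) -> pd.DataFrame:
    """Join unit provider counts with populations and form densities.

    ``counts``: ``unit_id``, ``provider_count``.  ``populations``: first
    column the unit id, second the population.  Output adds
    ``density_per_1000`` (NaN when population is 0), ``has_service``,
    and ``excluded`` (True for zero-population units).
    """
    pop = populations.copy()
    pop.columns = ["unit_id", "population"]
    if (pop["population"] < 0).any():
        bad = pop.loc[pop["population"] < 0, "unit_id"].tolist()
        raise ValueError(f"negative population for unit(s): {bad}")
    missing = set(counts["unit_id"]) - set(pop["unit_id"])
    if missing:
        raise ValueError(f"units missing population entries: {sorted(missing)[:5]}")

    out = counts.merge(pop, on="unit_id", how="left", validate="1:1")
    popv = out["population"].to_numpy(dtype=float)
    cnt = out["provider_count"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(popv > 0, per * cnt / popv, np.nan)
    out["density_per_1000"] = dens
    out["has_service"] = out["provider_count"] > 0
    out["excluded"] = popv == 0
    return out.sort_values("unit_id").reset_index(drop=True)


def summarize(records: pd.DataFrame, include_zero_density: bool = True) -> DensitySummary:
    """Median and IQR of defined densities.

    ``include_zero_density=False`` restricts to units with service.
    Quartiles use linear interpolation between order statistics.
    """
    sel = records[~records["excluded"]]
    if not include_zero_density:
        sel = sel[sel["has_service"]]
    vals = sel["density_per_1000"].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return DensitySummary(0, None, None, None)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return DensitySummary(int(vals.size), float(med), float(q1), float(q3))


def uncovered_fraction(records: pd.DataFrame) -> tuple[int, int, float]:
    """(m, n, m/n): units without service over all units."""
    if len(records) == 0:
        raise ValueError("uncovered_fraction: no records")
    m = int((~records["has_service"]).sum())
    n = int(len(records))
    return m, n, m / n


def rank_table(
    density: pd.DataFrame,
    smoking: pd.DataFrame,
    by: str = "density",
    direction: str = "top",
    k: int = 10,
) -> pd.DataFrame:
    """Top/bottom-k counties by density or smoking prevalence.

    Ranking by density excludes no-service counties (so bottom-k lists
    strictly positive densities); ranking by smoking keeps them, showing
    the density column as "not available".  Ties break by county id.
    """
    if by not in ("density", "smoking"):
        raise ValueError(f"rank_table: by must be 'density' or 'smoking', got {by!r}")
    if direction not in ("top", "bottom"):
        raise ValueError(f"rank_table: direction must be 'top' or 'bottom', got {direction!r}")

    merged = density.rename(columns={"unit_id": "county_id"}).merge(
        smoking, on="county_id", how="inner", validate="1:1"
    )
    merged = merged[~merged["excluded"]]
    if by == "density":
        merged = merged[merged["has_service"]]
        key = "density_per_1000"
    else:
        key = "smoking_prev_pct"

    ascending = direction == "bottom"
    merged = merged.sort_values([key, "county_id"], ascending=[ascending, True])
    if k > len(merged):
        warnings.warn(f"rank_table: k={k} exceeds {len(merged)} available units; truncated")
    sel = merged.head(k)

    dens_col = [
        float(d) if h else NOT_AVAILABLE
        for d, h in zip(sel["density_per_1000"], sel["has_service"])
    ]
    return pd.DataFrame(
        {
            "county_id": sel["county_id"].to_numpy(),
            "density_per_1000": dens_col,
            "smoking_prev_pct": sel["smoking_prev_pct"].to_numpy(),
        }
    ).reset_index(drop=True)
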