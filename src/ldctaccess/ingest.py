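"""Provider utilization ingest.

Reads the provider-level utilization table (one row per provider x
procedure code), restricts to the screening procedure code, sums service
counts per provider id, and re-applies the public-use file's privacy
floor: providers with fewer than ``min_services`` total services are
dropped.  Re-applying the floor explicitly (rather than trusting the
source) makes the suppression semantics identical for synthetic and real
inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("npi", "hcpcs_code", "line_srvc_cnt", "longitude", "latitude")
DEFAULT_CODE = "G0297"
DEFAULT_MIN_SERVICES = 11


class SchemaError(ValueError):
    """Input table violates the required schema."""


@dataclass
class RowError:
    line: int  # 1-based line number in the CSV (header = line 1)
    message: str


@dataclass
class LoadResult:
    rows: pd.DataFrame
    errors: list[RowError]


@dataclass
class ProviderSummary:
    n_providers: int
    total_services: int
    mean: float | None
    sd: float | None
    median: float | None
    min: int | None
    max: int | None

    @property
    def defined(self) -> bool:
        return self.n_providers > 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def load_provider_table(path: str | Path) -> LoadResult:
    """Parse the provider CSV; malformed rows are collected, not fatal.

    Raises :class:`SchemaError` naming the column if a required column is
    absent.  Rows with non-numeric or out-of-range coordinates, or
    negative/non-integer service counts, are dropped and reported with
    their 1-based file line numbers.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")

    errors: list[RowError] = []
    keep = np.ones(len(raw), dtype=bool)

    def _reject(i: int, msg: str) -> None:
        keep[i] = False
        errors.append(RowError(line=i + 2, message=msg))

    lon = pd.to_numeric(raw["longitude"], errors="coerce")
    lat = pd.to_numeric(raw["latitude"], errors="coerce")
    cnt = pd.to_numeric(raw["line_srvc_cnt"], errors="coerce")
    for i in range(len(raw)):
        if np.isnan(lon.iat[i]) or np.isnan(lat.iat[i]):
            _reject(i, "non-numeric coordinate")
        elif not (-180.0 <= lon.iat[i] <= 180.0) or not (-90.0 <= lat.iat[i] <= 90.0):
            _reject(i, f"coordinate out of range: lon={lon.iat[i]}, lat={lat.iat[i]}")
        elif np.isnan(cnt.iat[i]) or cnt.iat[i] < 0 or cnt.iat[i] != int(cnt.iat[i]):
            _reject(i, f"invalid service count: {raw['line_srvc_cnt'].iat[i]!r}")

    rows = pd.DataFrame(
        {
            "npi": raw["npi"][keep].astype(str),
            "hcpcs_code": raw["hcpcs_code"][keep].astype(str),
            "line_srvc_cnt": cnt[keep].astype(int),
            "longitude": lon[keep],
            "latitude": lat[keep],
        }
    ).reset_index(drop=True)
    return LoadResult(rows=rows, errors=errors)


def filter_and_aggregate(
    rows: pd.DataFrame,
    code: str = DEFAULT_CODE,
    min_services: int = DEFAULT_MIN_SERVICES,
) -> pd.DataFrame:
    """Keep rows with the screening code, sum counts per provider, and
    drop providers below the privacy floor.

    Returns provider records (``provider_id``, ``lon``, ``lat``,
    ``total_services``) sorted by provider id.  A provider appearing with
    conflicting coordinates is a fatal data-integrity error: silently
    averaging could move the provider across a buffer boundary.
    """
    sel = rows[rows["hcpcs_code"] == code]
    if sel.empty:
        return pd.DataFrame(columns=["provider_id", "lon", "lat", "total_services"])

    coords = sel.groupby("npi")[["longitude", "latitude"]].nunique()
    bad = coords[(coords["longitude"] > 1) | (coords["latitude"] > 1)].index.tolist()
    if bad:
        raise ValueError(f"conflicting coordinates for provider(s): {bad}")

    agg = (
        sel.groupby("npi")
        .agg(
            lon=("longitude", "first"),
            lat=("latitude", "first"),
            total_services=("line_srvc_cnt", "sum"),
        )
        .reset_index()
        .rename(columns={"npi": "provider_id"})
    )
    agg = agg[agg["total_services"] >= min_services]
    return agg.sort_values("provider_id").reset_index(drop=True)[
        ["provider_id", "lon", "lat", "total_services"]
    ]


def provider_summary(records: pd.DataFrame, sd_convention: str = "population") -> ProviderSummary:
    """Descriptive statistics of per-provider service totals.

    ``sd_convention`` is "population" (divide by n, the convention of
    mean +/- sd descriptive reporting) or "sample" (n-1).
    """
    if len(records) == 0:
        return ProviderSummary(0, 0, None, None, None, None, None)
    counts = records["total_services"].to_numpy(dtype=float)
    ddof = 0 if sd_convention == "population" else 1
    sd = float(np.std(counts, ddof=ddof)) if len(counts) > ddof else 0.0
    return ProviderSummary(
        n_providers=int(len(counts)),
        total_services=int(counts.sum()),
        mean=float(counts.mean()),
        sd=sd,
        median=float(np.median(counts)),
        min=int(counts.min()),
        max=int(counts.max()),
    )
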