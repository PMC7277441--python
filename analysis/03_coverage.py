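#!/usr/bin/env python
"""Buffer each provider by 30 miles and count tract/county coverage.

A tract is served when more than 51% of its area falls inside a
provider's buffer; county counts sum the member-tract counts.  Writes
coverage.csv, tract_counts.csv, county_counts.csv into results/run/.
"""

from pathlib import Path

from ldctaccess.config import RunConfig
from ldctaccess.pipeline import stage_coverage

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    cfg = RunConfig(indir=str(RUN), outdir=str(RUN))
    cov, tract_counts, county_counts = stage_coverage(cfg)
    n_pairs = int(cov["served"].sum())
    n_tracts_served = int((tract_counts["provider_count"] > 0).sum())
    n_counties_served = int((county_counts["provider_count"] > 0).sum())
    print(f"{n_pairs} served (provider, tract) pairs.")
    print(f"{n_tracts_served}/{len(tract_counts)} tracts have at least one "
          f"provider within reach; {len(tract_counts) - n_tracts_served} have none.")
    print(f"{n_counties_served}/{len(county_counts)} counties have any service.")


if __name__ == "__main__":
    main()
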