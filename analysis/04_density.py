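#!/usr/bin/env python
"""Provider densities per 1000 beneficiaries, summaries, rank tables.

Writes density_tract.csv, density_county.csv, summary.json and
rank_tables.csv into results/run/ and narrates the headline numbers.
"""

import json
from pathlib import Path

from ldctaccess.config import RunConfig
from ldctaccess.pipeline import stage_density

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    cfg = RunConfig(indir=str(RUN), outdir=str(RUN))
    stage_density(cfg)
    s = json.loads((RUN / "summary.json").read_text())
    tu, cu = s["tracts_uncovered"], s["counties_no_service"]
    print(f"{100 * tu['fraction']:.1f}% of tracts ({tu['m']}/{tu['n']}) have no "
          "provider serving them.")
    print(f"{100 * cu['fraction']:.1f}% of counties ({cu['m']}/{cu['n']}) have no "
          "screening service at all.")
    ca, cs = s["county_all"], s["county_served"]
    print(f"County density: median {ca['median']:.2f} per 1000 "
          f"(IQR {ca['q1']:.2f}-{ca['q3']:.2f}) over all {ca['n']} counties;")
    print(f"restricted to the {cs['n']} served counties, median {cs['median']:.2f} "
          f"(IQR {cs['q1']:.2f}-{cs['q3']:.2f}).")
    print("Top/bottom-10 rankings by density and smoking: rank_tables.csv")


if __name__ == "__main__":
    main()
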