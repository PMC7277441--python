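#!/usr/bin/env python
"""Export the class-coded map layer, scatter data, and run report.

Writes map_layer.geojson, scatter.csv, report.md and (with rendering
enabled) static choropleth PNGs into results/run/.
"""

from pathlib import Path

from ldctaccess.config import RunConfig
from ldctaccess.pipeline import stage_report

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    cfg = RunConfig(indir=str(RUN), outdir=str(RUN), render=True)
    report = stage_report(cfg)
    print(f"Run report: {report}")
    print((RUN / "report.md").read_text())


if __name__ == "__main__":
    main()
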