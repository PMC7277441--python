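"""Run configuration.

Defaults are exactly the reference analysis parameters (30-mile buffer,
strict 51% served rule, G0297, 11-service floor, per-1000 densities,
tertile breaks at the 34th/67th percentiles).  Any departure must be
requested explicitly and is labelled in the run report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path


@dataclass
class RunConfig:
    seed: int | None = None
    indir: str = "."
    outdir: str = "."
    buffer_radius_miles: float = 30.0
    area_fraction_threshold: float = 0.51
    min_services: int = 11
    procedure_code: str = "G0297"
    per_capita: int = 1000
    tertile_breaks: tuple[float, float] = (34.0, 67.0)
    projection: str = "albers_equal_area"
    distinct_providers: bool = False
    include_zero_density: bool = True
    percentile_method: str = "midrank"
    render: bool = False
    scenario_overrides: dict = field(default_factory=dict)

    # analysis parameters whose defaults define the reference configuration
    _REFERENCE_FIELDS = (
        "buffer_radius_miles",
        "area_fraction_threshold",
        "min_services",
        "procedure_code",
        "per_capita",
        "tertile_breaks",
        "distinct_providers",
        "percentile_method",
    )

    def validate(self) -> None:
        if self.buffer_radius_miles <= 0:
            raise ValueError("buffer_radius_miles must be positive")
        if not 0.0 <= self.area_fraction_threshold < 1.0:
            raise ValueError("area_fraction_threshold must lie in [0, 1)")
        if self.min_services < 0:
            raise ValueError("min_services must be >= 0")
        if self.per_capita <= 0:
            raise ValueError("per_capita must be positive")
        lo, hi = self.tertile_breaks
        if not 0 < lo < hi < 100:
            raise ValueError("tertile_breaks must satisfy 0 < low < high < 100")
        if self.percentile_method not in ("midrank", "ecdf"):
            raise ValueError("percentile_method must be 'midrank' or 'ecdf'")

    def deviations(self) -> list[str]:
        """Analysis parameters that differ from the reference values."""
        ref = RunConfig()
        return [
            f for f in self._REFERENCE_FIELDS if getattr(self, f) != getattr(ref, f)
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tertile_breaks"] = list(self.tertile_breaks)
        return d


def _coerce(name: str, value: str):
    conv = {
        "seed": int,
        "buffer_radius_miles": float,
        "area_fraction_threshold": float,
        "min_services": int,
        "per_capita": int,
        "distinct_providers": lambda v: v.lower() in ("1", "true", "yes"),
        "include_zero_density": lambda v: v.lower() in ("1", "true", "yes"),
        "render": lambda v: v.lower() in ("1", "true", "yes"),
        "tertile_breaks": lambda v: tuple(float(x) for x in v.split(",")),
    }
    return conv.get(name, str)(value)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a simple ``key = value`` config file (# comments allowed)."""
    cfg = RunConfig()
    known = {f.name for f in fields(RunConfig)}
    scenario: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("scenario."):
            scenario[key.removeprefix("scenario.")] = value
        elif key in known:
            setattr(cfg, key, _coerce(key, value))
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    cfg.scenario_overrides = scenario
    for key, value in overrides.items():
        if value is not None:
            setattr(cfg, key, value)
    cfg.validate()
    return cfg
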