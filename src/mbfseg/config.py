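"""Pipeline configuration: every tunable constant in one schema-checked
place, loadable from YAML with embedded defaults.  Unknown keys are
rejected so typos fail loudly.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .errors import SchemaError
from .landmarks import LandmarkParams
from .mapseg import MapSegParams
from .perfseg import PerfSegParams, SnakeParams


@dataclass(frozen=True)
class SectorParams:
    n_sectors: int = 6
    direction: str = "ccw"


@dataclass(frozen=True)
class PipelineConfig:
    landmarks: LandmarkParams = field(default_factory=LandmarkParams)
    perfseg: PerfSegParams = field(default_factory=PerfSegParams)
    mapseg: MapSegParams = field(default_factory=MapSegParams)
    sectors: SectorParams = field(default_factory=SectorParams)
    rng_seed: int = 0
    output_dir: str = "."


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise SchemaError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if isinstance(value, dict):
            sub = {"landmarks": LandmarkParams, "perfseg": PerfSegParams,
                   "mapseg": MapSegParams, "sectors": SectorParams,
                   "snake": SnakeParams, "perf": PerfSegParams}.get(name)
            if sub is None:
                raise SchemaError(f"unexpected mapping at {path}.{name}")
            kwargs[name] = _build(sub, value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path=None) -> PipelineConfig:
    """Load a PipelineConfig from YAML; missing keys keep their defaults."""
    if path is None:
        return PipelineConfig()
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise SchemaError("config root must be a mapping")
    return _build(PipelineConfig, data, "config")
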