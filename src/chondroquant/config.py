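"""Run configuration: one JSON document describing phantom, fit, VOI and
statistics options.  Unknown keys are rejected so typos fail loudly."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .longstats import StatsConfig
from .phantom import PhantomSpec, ProgressionModel

__all__ = ["FitOptions", "VOIOptions", "RunConfig"]


@dataclass
class FitOptions:
    exclude_first: bool = True
    method: str = "loglinear"  # or 'nonlinear'
    quantile_method: str = "linear"  # IQR quantile convention (numpy names)
    raya_order: str = "negatives_first"  # or 'pooled'


@dataclass
class VOIOptions:
    ap_fractions: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    ml_fractions: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    coverage_cap: float = 8.0
    include_layers: bool = False  # add per-layer T2 medians to the table


def _build(cls, data: dict, path: str):
    """Construct a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected an object")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        if name in _NESTED:
            kwargs[name] = _build(_NESTED[name], value, f"{path}.{name}")
        elif isinstance(value, list) and isinstance(f.default, tuple):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    "phantom": PhantomSpec,
    "progression": ProgressionModel,
    "fit": FitOptions,
    "voi": VOIOptions,
    "stats": StatsConfig,
}


@dataclass
class RunConfig:
    """Full configuration of an end-to-end run, serializable to one JSON."""

    outdir: str = "results"
    seed: int = 0
    n_knees: int = 19
    render: bool = True
    save_images: bool = False  # also write volumes and meshes per knee
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    progression: ProgressionModel = field(default_factory=ProgressionModel)
    fit: FitOptions = field(default_factory=FitOptions)
    voi: VOIOptions = field(default_factory=VOIOptions)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data, "config")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            return obj

        return convert(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def canonical_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()
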