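"""Run configuration: one YAML file driving the whole pipeline.

Defaults mirror the embryonic study conditions (bf = 0.2, k = 0.5, growth
radii 2.5 / 1.81 µm, 100,000 probe points, hourly retraction bins between
16.5 and 21.5 hrs AEL, target normalization area 100 µm²).  Every value is
validated against the owning module's preconditions at load time; CLI
flags override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .growth import GrowthParams
from .synthetic import CombParams, PeristalsisParams, TimelapseParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "combmorph_out"
    resample_spacing_small: float = 0.1   # trees below the length threshold
    resample_spacing_large: float = 1.0   # trees above it
    resample_length_threshold: float = 400.0
    target_area: float = 100.0
    spanning_area_method: str = "convex"
    mesh: float = 1.0                     # space-filling mesh (µm)
    tracking_resolution: float = 0.3      # optical resolution floor (µm)
    n_boot: int = 10_000
    mst_n_sims: int = 100
    mst_max_targets: int = 500
    mst_bf: float = 0.2
    mst_checkpoint_step: int = 25
    mst_region: str = "square"
    growth: GrowthParams = field(default_factory=GrowthParams)
    comb: CombParams = field(default_factory=CombParams)
    timelapse: TimelapseParams = field(default_factory=TimelapseParams)
    peristalsis: PeristalsisParams = field(default_factory=PeristalsisParams)

    def __post_init__(self):
        if self.resample_spacing_small <= 0 or self.resample_spacing_large <= 0:
            raise ValueError("resample spacings must be positive")
        if self.target_area <= 0:
            raise ValueError("target_area must be positive")
        if self.spanning_area_method not in ("convex", "concave"):
            raise ValueError("spanning_area_method must be convex or concave")
        if self.n_boot < 1000:
            raise ValueError("n_boot must be at least 1000")
        if not 0 <= self.mst_bf <= 1:
            raise ValueError("mst_bf must lie in [0, 1]")

    def resample_spacing(self, total_length: float) -> float:
        """Spacing rule: fine spacing below the length threshold, coarse
        above (applied per reconstruction)."""
        return (
            self.resample_spacing_small
            if total_length < self.resample_length_threshold
            else self.resample_spacing_large
        )


def _to_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"unknown {cls.__name__} option {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; ``overrides`` (flat dict, nested keys dotted as
    ``growth.b_r``) take precedence over file values."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        d = data
        for part in parts[:-1]:
            d = d.setdefault(part, {})
        d[parts[-1]] = value
    sub = {
        "growth": GrowthParams,
        "comb": CombParams,
        "timelapse": TimelapseParams,
        "peristalsis": PeristalsisParams,
    }
    kwargs = {}
    for key, value in data.items():
        if key in sub:
            kwargs[key] = _build(sub[key], value or {})
        else:
            kwargs[key] = value
    return _build(RunConfig, {**kwargs})
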