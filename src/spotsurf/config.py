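"""Strict YAML-backed pipeline configuration.

Configs are plain nested dataclasses; loading rejects unknown keys so that
typos fail loudly instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = [
    "GeometrySection", "BackgroundSection", "DetectSection", "NullSection",
    "BinsSection", "KernelSection", "NoiseSection", "SimulateSection",
    "PipelineConfig", "load_config", "config_hash",
]


@dataclass
class GeometrySection:
    shape_voxels: list = field(default_factory=lambda: [60, 256, 256])
    spacing_um: list = field(default_factory=lambda: [0.2, 0.299, 0.299])


@dataclass
class BackgroundSection:
    filter_width_um: float = 46.2
    clamp_negative: bool = True


@dataclass
class DetectSection:
    spot_diameter_um: float = 0.723
    threshold: float = 10.0
    surface_threshold: float = 50.0
    min_component_voxels: int = 10
    smoothing_detail_um: float = 0.145


@dataclass
class NullSection:
    n_sims: int = 1000
    exclude_interior: bool = True


@dataclass
class BinsSection:
    coarse: list = field(default_factory=lambda: [0, 5, 10, 15, 20, 25, 30])
    fine: list = field(default_factory=lambda: list(range(16)))


@dataclass
class KernelSection:
    radius_um: float = 7.0
    amplitude: float = 1.0
    profile: str = "flat"


@dataclass
class NoiseSection:
    background_level: float = 0.0
    background_smoothness_um: float = 5.0
    photon_scale: float = 0.0  # 0 means "no shot noise"
    read_sigma: float = 0.0


@dataclass
class SimulateSection:
    n_neurons: int = 1
    n_spots: int = 300
    n_branches: int = 5
    branch_length_um: float = 15.0
    soma_radius_um: float = 4.0
    tube_radius_um: float = 0.4
    spot_peak: float = 100.0
    render: bool = True
    kernel: KernelSection = field(default_factory=KernelSection)
    noise: NoiseSection = field(default_factory=NoiseSection)


@dataclass
class PipelineConfig:
    geometry: GeometrySection = field(default_factory=GeometrySection)
    background: BackgroundSection = field(default_factory=BackgroundSection)
    detect: DetectSection = field(default_factory=DetectSection)
    null: NullSection = field(default_factory=NullSection)
    bins: BinsSection = field(default_factory=BinsSection)
    simulate: SimulateSection = field(default_factory=SimulateSection)
    alpha: float = 0.05
    seed: int = 0


def _from_dict(cls, data, path="config"):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    # a bare `null:` key in YAML parses as None; map it back to the section name
    data = {("null" if k is None else k): v for k, v in data.items()}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = _SECTION_TYPES.get(name)
        if sub is not None and isinstance(value, (dict, type(None))):
            kwargs[name] = _from_dict(sub, value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SECTION_TYPES = {
    "geometry": GeometrySection,
    "background": BackgroundSection,
    "detect": DetectSection,
    "null": NullSection,
    "bins": BinsSection,
    "simulate": SimulateSection,
    "kernel": KernelSection,
    "noise": NoiseSection,
}


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    return _from_dict(PipelineConfig, data)


def dump_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True))


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the full configuration, for provenance logging."""
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
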