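"""Pipeline configuration: every tunable in one YAML-serializable object.

Defaults reproduce the acquisition and analysis settings of the study
conditions the simulator emulates (pixel size 0.106 μm, frame interval
5.477 ms, localization error 28 nm, detection depth 0.7 μm, two-state
diffusion bounds, control-region rules, bootstrap sizes).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .regions import ControlRegionParams
from .simulate import SimCamera, SimGeometry, SimKinetics


@dataclass
class TwoStateParams:
    """Settings of the two-state jump-length fit."""

    localization_error: float = 0.028  # μm, fixed in the fit
    dz: float = 0.7  # μm
    max_dt: int = 6
    max_jumps_per_traj: int = 3
    max_jump_length: float = 2.0  # μm
    bound_range: tuple[float, float] = (0.0, 0.02)
    free_range: tuple[float, float] = (0.1, 20.0)
    n_boot: int = 50
    boot_size: int = 3000


@dataclass
class AngleParams:
    """Settings of the jump-angle analysis."""

    min_jump: float = 0.2  # μm
    max_jump: float = 3.0  # μm
    bin_width: float = 10.0  # degrees
    max_jumps_per_traj: int = 100
    forward_window: tuple[float, float] = (0.0, 30.0)
    backward_window: tuple[float, float] = (160.0, 180.0)
    n_boot: int = 50
    boot_size: int = 250


@dataclass
class FrapParams:
    bleach_frame: int = 80
    use_exponential_fits: bool = True


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with a lossless YAML round trip."""

    geometry: SimGeometry = field(default_factory=SimGeometry)
    kinetics: SimKinetics = field(default_factory=SimKinetics)
    camera: SimCamera = field(default_factory=SimCamera)
    controls: ControlRegionParams = field(default_factory=ControlRegionParams)
    two_state: TwoStateParams = field(default_factory=TwoStateParams)
    angles: AngleParams = field(default_factory=AngleParams)
    frap: FrapParams = field(default_factory=FrapParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return _listify(dataclasses.asdict(self))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in _SECTION_TYPES:
                section = _SECTION_TYPES[f.name]
                value = section(**_tuplify(section, value))
            kwargs[f.name] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


_SECTION_TYPES = {
    "geometry": SimGeometry,
    "kinetics": SimKinetics,
    "camera": SimCamera,
    "controls": ControlRegionParams,
    "two_state": TwoStateParams,
    "angles": AngleParams,
    "frap": FrapParams,
}


def _listify(obj):
    """Tuples → lists so yaml.safe_dump emits plain sequences."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def _tuplify(section_type, data: dict) -> dict:
    """Lists back to tuples where the dataclass default is a tuple."""
    out = {}
    defaults = section_type()
    for k, v in data.items():
        ref = getattr(defaults, k, None)
        if isinstance(ref, tuple) and isinstance(v, list):
            v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        out[k] = v
    return out
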