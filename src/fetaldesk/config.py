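"""YAML run configuration.

One nested document configures every stage; section keys mirror the
parameter dataclasses.  Unknown keys are rejected so typos never silently fall back to
defaults.  The defaults are the device's printed operating parameters:
detrend pole 0.99, movement threshold 0.002 g, front-end gain 2 with a
200 Hz fourth-order low-pass, 300 ms beat refractory, 6-s count×10 FHR
windows, 120–160 bpm normal band, 4500 s no-movement timeout.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .distress_logic import DistressThresholds
from .errors import ConfigError
from .fm_detection import DetrendFilterSpec, PeakDetectorConfig
from .fpcg_chain import BeatDetectorConfig, FrontEndSpec
from .synth_signals import SynthAccelConfig, SynthPcgConfig


@dataclass(frozen=True)
class RunConfig:
    detrend: DetrendFilterSpec = field(default_factory=DetrendFilterSpec)
    peaks: PeakDetectorConfig = field(default_factory=PeakDetectorConfig)
    frontend: FrontEndSpec = field(default_factory=FrontEndSpec)
    beats: BeatDetectorConfig = field(default_factory=BeatDetectorConfig)
    thresholds: DistressThresholds = field(default_factory=DistressThresholds)
    synth_accel: SynthAccelConfig = field(default_factory=SynthAccelConfig)
    synth_pcg: SynthPcgConfig = field(default_factory=SynthPcgConfig)
    units_scale: float = 1.0
    match_window: float = 5.0
    cooldown: float = 600.0
    log_level: str = "INFO"
    seed: int = 0


_SECTIONS = {
    "detrend": DetrendFilterSpec,
    "peaks": PeakDetectorConfig,
    "frontend": FrontEndSpec,
    "beats": BeatDetectorConfig,
    "thresholds": DistressThresholds,
    "synth_accel": SynthAccelConfig,
    "synth_pcg": SynthPcgConfig,
}
_SCALARS = {"units_scale", "match_window", "cooldown", "log_level", "seed"}


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def config_from_dict(data: dict) -> RunConfig:
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ConfigError(f"unknown top-level config key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data[name]
            if not isinstance(section, dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    for name in _SCALARS:
        if name in data:
            kwargs[name] = data[name]
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse YAML config {path}: {e}") from e
    return config_from_dict(data)


def dump_config(cfg: RunConfig) -> dict:
    """The effective configuration as a plain dict (YAML/JSON ready)."""
    return dataclasses.asdict(cfg)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the effective configuration, for run logs."""
    canonical = json.dumps(dump_config(cfg), sort_keys=True, default=list)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
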