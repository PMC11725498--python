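"""Run configuration: TOML schema with defaults, validation, and dumping."""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from tetherlab.errors import ConfigError
from tetherlab.link import LinkConfig


@dataclass
class LinkSection:
    bandwidth_bytes_per_s: float = 150e6
    block_size_bytes: int = 8192
    per_transfer_overhead_s: float = 0.0

    def to_link_config(self) -> LinkConfig:
        return LinkConfig(
            link_bandwidth_bytes_per_s=self.bandwidth_bytes_per_s,
            block_size_bytes=self.block_size_bytes,
            per_transfer_overhead_s=self.per_transfer_overhead_s,
        )


@dataclass
class CommutatorSection:
    threshold_turns: float = 0.25
    step_deg: float = 1.8


@dataclass
class BehaviorSection:
    occupancy_bins: int = 20
    heading_bins: int = 40
    stationary_threshold_m_s: float = 0.02
    time_bin_s: float = 60.0
    n_boot: int = 1000


@dataclass
class PathsSection:
    input: str = ""
    out_dir: str = "out"


@dataclass
class RunConfig:
    seed: int = 0
    clock_hz: float = 30_000.0
    link: LinkSection = field(default_factory=LinkSection)
    commutator: CommutatorSection = field(default_factory=CommutatorSection)
    behavior: BehaviorSection = field(default_factory=BehaviorSection)
    paths: PathsSection = field(default_factory=PathsSection)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "link": LinkSection,
    "commutator": CommutatorSection,
    "behavior": BehaviorSection,
    "paths": PathsSection,
}
_SCALARS = {"seed": int, "clock_hz": float}


def _build_section(cls, data: dict, section_name: str):
    known = {f.name: f.type for f in fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown key '{section_name}.{key}'")
    obj = cls(**data)
    return obj


def config_from_dict(data: dict) -> RunConfig:
    cfg = RunConfig()
    for key, value in data.items():
        if key in _SCALARS:
            setattr(cfg, key, _SCALARS[key](value))
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section '{key}' must be a table")
            setattr(cfg, key, _build_section(_SECTIONS[key], value, key))
        else:
            raise ConfigError(f"unknown key '{key}'")
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    if cfg.clock_hz <= 0:
        raise ConfigError("'clock_hz' must be positive")
    if cfg.link.block_size_bytes < 1:
        raise ConfigError("'link.block_size_bytes' must be >= 1")
    if cfg.link.bandwidth_bytes_per_s <= 0:
        raise ConfigError("'link.bandwidth_bytes_per_s' must be positive")
    if cfg.link.per_transfer_overhead_s < 0:
        raise ConfigError("'link.per_transfer_overhead_s' must be >= 0")
    if cfg.commutator.threshold_turns <= 0:
        raise ConfigError("'commutator.threshold_turns' must be positive")
    if cfg.commutator.step_deg <= 0:
        raise ConfigError("'commutator.step_deg' must be positive")
    if cfg.behavior.n_boot < 1:
        raise ConfigError("'behavior.n_boot' must be >= 1")
    if cfg.behavior.time_bin_s <= 0:
        raise ConfigError("'behavior.time_bin_s' must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration, filling defaults."""
    raw = Path(path).read_bytes()
    try:
        data = tomllib.loads(raw.decode())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML: {exc}") from exc
    return config_from_dict(data)


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    return '"' + str(value).replace("\\", "\\\\").replace('"', '\\"') + '"'


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig to TOML (normal form: every key explicit)."""
    lines = []
    d = cfg.to_dict()
    for key in _SCALARS:
        lines.append(f"{key} = {_toml_scalar(d[key])}")
    for section in _SECTIONS:
        lines.append("")
        lines.append(f"[{section}]")
        for k, v in d[section].items():
            lines.append(f"{k} = {_toml_scalar(v)}")
    return "\n".join(lines) + "\n"
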