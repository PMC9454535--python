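"""YAML/JSON pipeline configuration with field-path validation.

One config file carries every tunable threshold; the defaults equal the
documented study values, so a bare run reproduces the standard cascade.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .acmg import AcmgConfig
from .io import LlskitError, ValidationError
from .prioritization import FilterConfig
from .synthetic_cohort import SimConfig


class ConfigError(LlskitError):
    """Config schema or domain violation; message carries the field path."""


_SECTIONS = {"simulate": SimConfig, "filters": FilterConfig, "acmg": AcmgConfig}


@dataclass(frozen=True)
class PipelineConfig:
    simulate: SimConfig = field(default_factory=SimConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    acmg: AcmgConfig = field(default_factory=AcmgConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the config, independent of field order."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build_section(name: str, cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"{name}: expected a mapping, got {type(data).__name__}")
    valid_fields = set(cls.__dataclass_fields__)
    unknown = set(data) - valid_fields
    if unknown:
        raise ConfigError(f"{name}.{sorted(unknown)[0]}: unknown field")
    try:
        return cls(**data)
    except (ValidationError, TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a pipeline config; None yields all defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"{sorted(unknown)[0]}: unknown section")
    sections = {
        name: _build_section(name, cls, raw.get(name, {}))
        for name, cls in _SECTIONS.items()
    }
    return PipelineConfig(**sections)
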