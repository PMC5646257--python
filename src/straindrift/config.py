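"""Pipeline configuration: TOML files with CLI-flag overrides (flags win)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .cargo import CargoCriteria
from .errors import DataError
from .founder import ConversionConstants, ReactorGeometry
from .synthetic import ReactorParams
from .variants import FilterThresholds

__all__ = ["PipelineConfig", "load_config"]

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass(frozen=True)
class PipelineConfig:
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    criteria: CargoCriteria = field(default_factory=CargoCriteria)
    geometry: ReactorGeometry = field(default_factory=ReactorGeometry)
    constants: ConversionConstants = field(default_factory=ConversionConstants)
    reactor: ReactorParams = field(default_factory=ReactorParams)
    seed: int = 0
    output_dir: str = "straindrift_out"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.log_level not in _LOG_LEVELS:
            raise DataError(f"log_level must be one of {_LOG_LEVELS}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Digest of the scientific parameters (paths and logging excluded,
        so reruns into different directories stay byte-identical)."""
        d = self.as_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise DataError(f"unknown keys in [{name}]: {sorted(unknown)}")
    try:
        return cls(**section)
    except TypeError as exc:
        raise DataError(f"bad [{name}] section: {exc}") from exc


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a TOML config; keyword overrides (e.g. from CLI flags) win
    over the file, which wins over defaults."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise DataError(f"config file not found: {path}")
        try:
            data = tomllib.loads(path.read_text())
        except tomllib.TOMLDecodeError as exc:
            raise DataError(f"malformed TOML in {path}: {exc}") from exc
    sections = {
        "thresholds": (FilterThresholds, data.get("thresholds", {})),
        "criteria": (CargoCriteria, data.get("criteria", {})),
        "geometry": (ReactorGeometry, data.get("geometry", {})),
        "constants": (ConversionConstants, data.get("constants", {})),
        "reactor": (ReactorParams, data.get("reactor", {})),
    }
    kwargs = {}
    for key, (cls, section) in sections.items():
        section = dict(section)
        section.update(overrides.pop(key, {}))
        # tuple-valued fields arrive from TOML as lists
        for k, v in section.items():
            if isinstance(v, list):
                section[k] = tuple(v)
        kwargs[key] = _build(cls, section, key)
    for scalar in ("seed", "output_dir", "log_level"):
        if scalar in overrides and overrides[scalar] is not None:
            kwargs[scalar] = overrides.pop(scalar)
        elif scalar in data:
            kwargs[scalar] = data[scalar]
    overrides.pop("seed", None), overrides.pop("output_dir", None), overrides.pop("log_level", None)
    if overrides:
        raise DataError(f"unknown config overrides: {sorted(overrides)}")
    return PipelineConfig(**kwargs)
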