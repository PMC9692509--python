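"""Run configuration: one validated record driving the whole pipeline.

A RunConfig bundles the geometry, flow, particle, magnet and tracing
settings; it round-trips losslessly through YAML, and its content hash is
recorded in every output for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .airflow import FlowParams
from .errors import ConfigurationError, NasomagError
from .geometry import SurrogateParams
from .magnetics import ParticleProps
from .tracing import TraceConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    geometry: SurrogateParams = field(default_factory=SurrogateParams)
    flow: FlowParams = field(default_factory=FlowParams)
    particle: ParticleProps = field(default_factory=ParticleProps)
    trace: TraceConfig = field(default_factory=TraceConfig)
    protocols: tuple = (1, 2, 3)
    include_baseline: bool = True
    baseline_release: int = 3  # release geometry reused for the control run
    particle_count: int = 100
    release_length: float = 0.015
    magnet_distance: float = 0.005
    magnet_center_yz: tuple = (0.015, 0.025)
    jitter_seed: int | None = None

    def __post_init__(self):
        for p in self.protocols:
            if p not in (1, 2, 3):
                raise ConfigurationError(f"protocols: unknown protocol {p!r}")
        if self.particle_count < 1:
            raise ConfigurationError("particle_count must be >= 1")
        if self.magnet_distance <= 0:
            raise ConfigurationError("magnet_distance must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["protocols"] = list(self.protocols)
        d["magnet_center_yz"] = list(self.magnet_center_yz)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        kwargs = {}
        for section, typ in (("geometry", SurrogateParams), ("flow", FlowParams),
                             ("particle", ParticleProps), ("trace", TraceConfig)):
            sub = raw.pop(section, {})
            if not isinstance(sub, dict):
                raise ConfigurationError(f"{section}: expected a mapping")
            valid = {f.name for f in fields(typ)}
            for key in sub:
                if key not in valid:
                    raise ConfigurationError(f"{section}.{key}: unknown field")
            try:
                kwargs[section] = typ(**sub)
            except (TypeError, ValueError, NasomagError) as exc:
                raise ConfigurationError(f"{section}: {exc}") from exc
        top_valid = {f.name for f in fields(cls)} - {
            "geometry", "flow", "particle", "trace"}
        for key in raw:
            if key not in top_valid:
                raise ConfigurationError(f"{key}: unknown field")
        if "protocols" in raw:
            raw["protocols"] = tuple(raw["protocols"])
        if "magnet_center_yz" in raw:
            raw["magnet_center_yz"] = tuple(raw["magnet_center_yz"])
        return cls(**kwargs, **raw)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.from_dict(raw)
    except ConfigurationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
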