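"""Run configuration: a plain-YAML description of a full pipeline run.

The config round-trips losslessly through YAML, rejects unknown keys, and
carries explicit per-stage seeds so all randomness is named.  A short hash
of the canonical serialization is stamped on every output a run produces.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

from .simulate import SimConfig

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class DEParams:
    min_total: int = 10
    q_threshold: float = 0.01
    min_fold: float = 2.0


@dataclass
class ModuleParams:
    n_modules: int = 2
    max_depth: int = 3
    min_leaf_conditions: int = 2
    max_iter: int = 20
    high_cut: float = 3.0
    low_cut: float = -3.0
    seed: int = 0


@dataclass
class ProteinParams:
    ref_channels: tuple = (4, 8)
    alpha: float = 0.05
    min_fold: float = 2.0
    global_correction: bool = False


@dataclass
class RunConfig:
    """All stage parameters of a pipeline run."""

    version: str = "1"
    seed: int = 1
    simulate: SimConfig = field(default_factory=SimConfig)
    de: DEParams = field(default_factory=DEParams)
    modules: ModuleParams = field(default_factory=ModuleParams)
    proteins: ProteinParams = field(default_factory=ProteinParams)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        sections = {"simulate": SimConfig, "de": DEParams,
                    "modules": ModuleParams, "proteins": ProteinParams}
        for key in list(data):
            if key in ("version", "seed"):
                kwargs[key] = data.pop(key)
            elif key in sections:
                sub = data.pop(key) or {}
                valid = {f.name for f in fields(sections[key])}
                unknown = set(sub) - valid
                if unknown:
                    raise ConfigError(
                        f"unknown key(s) in section '{key}': {', '.join(sorted(unknown))}"
                    )
                # YAML has no tuple type; normalise list-valued fields
                sub = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
                kwargs[key] = sections[key](**sub)
        if data:
            raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(data))}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        )

    def hash(self) -> str:
        canonical = yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj
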