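"""Configuration loading, validation and run manifests.

Every config file (JSON or YAML) carries a ``config_kind`` marker naming its
schema: ``hospital``, ``scenario_template``, ``fleet`` or ``policy``.
Validation is strict — unknown keys are errors, so typos never pass
silently — and the loaded object always has every default filled in
explicitly.  A :class:`RunManifest` records the hashes of all inputs plus the
seed; two runs with equal manifests produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .coordination import DistributionPolicy
from .engine import HospitalConfig
from .prehospital import AmbulanceFleet
from .scenario import ScenarioTemplate

__all__ = ["load_config", "save_config", "config_hash", "RunManifest", "ConfigFileError"]

_SCHEMAS = {
    "hospital": HospitalConfig,
    "scenario_template": ScenarioTemplate,
    "fleet": AmbulanceFleet,
    "policy": DistributionPolicy,
}

ConfigObject = Union[HospitalConfig, ScenarioTemplate, AmbulanceFleet, DistributionPolicy]


class ConfigFileError(ValueError):
    """A config file failed schema validation; the message names path and field."""


def load_config(path: str | Path) -> ConfigObject:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if not isinstance(data, dict) or "config_kind" not in data:
        raise ConfigFileError(f"{path}: missing 'config_kind' marker")
    kind = data.pop("config_kind")
    schema = _SCHEMAS.get(kind)
    if schema is None:
        raise ConfigFileError(f"{path}: unknown config_kind {kind!r} (expected one of {sorted(_SCHEMAS)})")
    try:
        return schema.model_validate(data)
    except ValidationError as err:
        fields = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ConfigFileError(f"{path}: invalid {kind} config — {fields}") from err


def save_config(obj: ConfigObject, path: str | Path) -> None:
    path = Path(path)
    for kind, schema in _SCHEMAS.items():
        if isinstance(obj, schema):
            data = {"config_kind": kind, **obj.model_dump(mode="json")}
            break
    else:
        raise TypeError(f"not a config object: {type(obj)!r}")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def config_hash(obj: BaseModel) -> str:
    """Stable sha256 over the canonical JSON form of a config object."""
    canon = json.dumps(obj.model_dump(mode="json"), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


class RunManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")

    command: str
    seed: int
    code_version: str = __version__
    config_hashes: dict[str, str] = Field(default_factory=dict)
    parameters: dict = Field(default_factory=dict)
    outputs: tuple[str, ...] = ()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls.model_validate(json.loads(Path(path).read_text()))
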