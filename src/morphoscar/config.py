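"""Configuration loading with strict key checking, plus run manifests.

Parameter sets and numerics configs are flat key->value YAML (JSON is valid
YAML and therefore also accepted).  Unknown keys are rejected loudly — a
typo in a rate constant should never silently fall back to a default — and
the derived parameters ``q`` and ``k_rho`` cannot be set at all.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path

import yaml

from . import __version__ as _pkg_version
from .fem import NumericsConfig
from .params import ParameterSet, validate_parameters, InvalidParameterError

__all__ = ["ConfigError", "load_parameters", "load_numerics",
           "save_parameters", "write_manifest", "atomic_write_text"]


class ConfigError(ValueError):
    """Malformed or inconsistent configuration file."""


_PARAM_KEYS = {f.name for f in dataclasses.fields(ParameterSet)}
_DERIVED_KEYS = {"q", "k_rho"}
_NUMERICS_KEYS = {f.name for f in dataclasses.fields(NumericsConfig)}


def _load_mapping(path) -> dict:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed YAML/JSON: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a key->value mapping")
    return data


def load_parameters(path, validate: bool = True) -> ParameterSet:
    """Read a ParameterSet from flat YAML/JSON; keys are the ASCII field
    names.  Validation runs automatically unless disabled."""
    data = _load_mapping(path)
    derived = _DERIVED_KEYS & data.keys()
    if derived:
        raise ConfigError(
            f"{path}: {sorted(derived)} are derived parameters and cannot "
            "be set directly")
    unknown = data.keys() - _PARAM_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown parameter keys {sorted(unknown)}")
    p = ParameterSet(**data)
    if validate:
        report = validate_parameters(p)
        if not report.ok:
            raise InvalidParameterError(
                f"{path}: parameter validation failed: "
                f"{report.to_dict()['violations']}")
    return p


def load_numerics(path) -> NumericsConfig:
    data = _load_mapping(path)
    unknown = data.keys() - _NUMERICS_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown numerics keys {sorted(unknown)}")
    return NumericsConfig(**data)


def save_parameters(p: ParameterSet, path) -> None:
    d = {k: v for k, v in dataclasses.asdict(p).items()
         if not hasattr(v, "__len__")}
    atomic_write_text(path, yaml.safe_dump(d, sort_keys=True))


def atomic_write_text(path, text: str) -> None:
    """Write via a temp file and rename, so readers never see partial
    output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    return obj


def config_hash(*objects) -> str:
    payload = json.dumps([_jsonable(o) for o in objects],
                         sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def write_manifest(out_dir, seed=None, **sections) -> Path:
    """Drop a manifest.json beside run outputs: package version, seed, and
    the full configs, enough to reproduce the run exactly."""
    out_dir = Path(out_dir)
    manifest = {"package": "morphoscar", "version": _pkg_version,
                "seed": seed}
    for name, obj in sections.items():
        if hasattr(obj, "to_dict"):
            manifest[name] = obj.to_dict()
        elif dataclasses.is_dataclass(obj):
            manifest[name] = dataclasses.asdict(obj)
        else:
            manifest[name] = obj
    manifest["config_hash"] = config_hash(
        *[v for k, v in manifest.items() if k not in ("package", "version")])
    path = out_dir / "manifest.json"
    atomic_write_text(path, json.dumps(manifest, indent=2, default=str))
    return path
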