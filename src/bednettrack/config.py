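"""Run configuration: strict YAML ↔ dataclass plumbing.

A run configuration bundles an optional ``scene`` section (simulate-then-
analyse mode), the ``segmentation`` and ``tracking`` parameter sections, a
seed and output options.  Loading is strict — unknown keys are rejected with
the offending path — and configurations round-trip exactly through
``save_run_config``/``load_run_config``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import types
import typing
from dataclasses import dataclass, field

import yaml

from bednettrack.scene import SceneConfig
from bednettrack.segmentation import SegmentationConfig
from bednettrack.tracking import TrackingConfig


class ConfigError(Exception):
    """Invalid or malformed run configuration (CLI exit code 2)."""


class DataError(Exception):
    """Invalid or unreadable input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Top-level configuration for one pipeline run."""

    scene: SceneConfig | None = None
    frames: str | None = None  # path to a frame stack, if not simulating
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.scene is None and self.frames is None:
            raise ConfigError("config needs either a 'scene' section or a 'frames' path")


def _to_plain(obj):
    """Dataclass tree → YAML-safe plain data (tuples become lists)."""
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _strip_optional(tp):
    if typing.get_origin(tp) in (typing.Union, types.UnionType):
        args = [a for a in typing.get_args(tp) if a is not type(None)]
        if len(args) == 1:
            return args[0]
    return tp


def _from_plain(cls, data, path: str = ""):
    """Plain mapping → dataclass, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping at {path or 'top level'}")
    hints = typing.get_type_hints(cls)
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}"
        )
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        tp = _strip_optional(hints[f.name])
        sub_path = f"{path}.{f.name}" if path else f.name
        if dataclasses.is_dataclass(tp) and isinstance(value, dict):
            value = _from_plain(tp, value, sub_path)
        elif typing.get_origin(tp) is list:
            (item_tp,) = typing.get_args(tp) or (None,)
            item_tp = _strip_optional(item_tp)
            if dataclasses.is_dataclass(item_tp) and value is not None:
                value = [
                    _from_plain(item_tp, v, f"{sub_path}[{i}]") if isinstance(v, dict) else v
                    for i, v in enumerate(value)
                ]
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {path or 'top level'}: {exc}") from exc


def run_config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(cfg)


def run_config_from_dict(data: dict) -> RunConfig:
    return _from_plain(RunConfig, data)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return run_config_from_dict(data or {})


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(run_config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Short provenance hash of the full configuration."""
    canon = yaml.safe_dump(run_config_to_dict(cfg), sort_keys=True)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]
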