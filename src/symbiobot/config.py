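"""TOML configuration: defaults, validation, serialization.

A config file holds up to seven tables -- ``[circuit]``, ``[noise]``,
``[efm]``, ``[robot]``, ``[arena]``, ``[engine]``, ``[sweep]`` -- whose
keys mirror the parameter dataclasses.  Missing keys fall back to the
reference defaults baked into those dataclasses; unknown tables or
keys are rejected with the offending key path.  The fully-resolved
config can be re-serialized so every output directory is
self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import tomllib
from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path
from typing import Any, Optional

from .circuits import CircuitParams, NoiseParams
from .engine import SimConfig
from .environment import ArenaParams
from .robot import RobotParams
from .transduction import EFMConfig

__all__ = ["ConfigError", "SweepOptions", "load_config", "load_sweep_options", "dump_config_toml", "config_hash"]


class ConfigError(ValueError):
    """A config file failed to parse or validate."""


@dataclass
class SweepOptions:
    """Resolutions of the two sweep drivers (``[sweep]`` table)."""

    grid_points: int = 10
    rbs_min: float = 0.05
    rbs_max: float = 1.0
    walk_points: int = 24
    walk_min: float = 1e-3
    walk_max: float = 0.9

    def __post_init__(self) -> None:
        if self.grid_points < 2 or self.walk_points < 2:
            raise ValueError("sweep resolutions must be >= 2")
        if not (0 < self.rbs_min <= self.rbs_max <= 1):
            raise ValueError("rbs sweep range must satisfy 0 < min <= max <= 1")
        if not (0 < self.walk_min <= self.walk_max <= 1):
            raise ValueError("walk range must satisfy 0 < min <= max <= 1")


#: table name -> (dataclass, SimConfig attribute or None for [engine]/[sweep])
_SECTIONS = {
    "circuit": CircuitParams,
    "noise": NoiseParams,
    "efm": EFMConfig,
    "robot": RobotParams,
    "arena": ArenaParams,
    "sweep": SweepOptions,
}
_ENGINE_KEYS = ("dt", "t_max", "seed", "ara_init")


def _build_section(name: str, cls: type, data: dict) -> Any:
    known = {f.name for f in fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown key [{name}].{key}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in [{name}]: {exc}") from exc


def _parse_document(doc: dict) -> tuple[SimConfig, SweepOptions]:
    for table in doc:
        if table not in _SECTIONS and table != "engine":
            raise ConfigError(f"unknown table [{table}]")
        if not isinstance(doc[table], dict):
            raise ConfigError(f"top-level key {table!r} must be a table")

    parts = {
        name: _build_section(name, cls, doc.get(name, {}))
        for name, cls in _SECTIONS.items()
    }
    engine = doc.get("engine", {})
    for key in engine:
        if key not in _ENGINE_KEYS:
            raise ConfigError(f"unknown key [engine].{key}")
    try:
        sim = SimConfig(
            circuit=parts["circuit"],
            noise=parts["noise"],
            efm=parts["efm"],
            robot=parts["robot"],
            arena=parts["arena"],
            **engine,
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in [engine]: {exc}") from exc
    return sim, parts["sweep"]


def _apply_overrides(doc: dict, overrides: dict[str, str]) -> None:
    """Apply ``table.key=value`` overrides onto the raw TOML document."""
    for path, raw in overrides.items():
        if path.count(".") != 1:
            raise ConfigError(f"override key must be 'table.key', got {path!r}")
        table, key = path.split(".")
        try:
            value = tomllib.loads(f"v = {raw}")["v"]
        except tomllib.TOMLDecodeError:
            value = raw  # bare string, e.g. topology=TOGGLE_LUX
        doc.setdefault(table, {})[key] = value


def load_config(
    path: Optional[str | Path] = None,
    overrides: Optional[dict[str, str]] = None,
) -> SimConfig:
    """Load and validate a simulation config (defaults if ``path`` is None)."""
    doc: dict = {}
    if path is not None:
        try:
            with open(path, "rb") as fh:
                doc = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if overrides:
        _apply_overrides(doc, overrides)
    sim, _ = _parse_document(doc)
    return sim


def load_sweep_options(path: Optional[str | Path] = None) -> SweepOptions:
    """Load just the ``[sweep]`` table (defaults if absent)."""
    doc: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    _, sweep = _parse_document(doc)
    return sweep


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, Enum):
        return f'"{v.value}"'
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, float):
        return repr(v)
    return str(v)


def dump_config_toml(cfg: SimConfig, sweep: Optional[SweepOptions] = None) -> str:
    """Serialize a fully-resolved config back to TOML text."""
    out: list[str] = []
    sections: list[tuple[str, Any]] = [
        ("circuit", cfg.circuit),
        ("noise", cfg.noise),
        ("efm", cfg.efm),
        ("robot", cfg.robot),
        ("arena", cfg.arena),
    ]
    if sweep is not None:
        sections.append(("sweep", sweep))
    for name, obj in sections:
        out.append(f"[{name}]")
        for f in fields(obj):
            out.append(f"{f.name} = {_toml_value(getattr(obj, f.name))}")
        out.append("")
    out.append("[engine]")
    for key in _ENGINE_KEYS:
        out.append(f"{key} = {_toml_value(getattr(cfg, key))}")
    out.append("")
    return "\n".join(out)


def config_hash(cfg: SimConfig) -> str:
    """Short stable digest of the resolved config."""
    return hashlib.sha256(dump_config_toml(cfg).encode()).hexdigest()[:16]
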