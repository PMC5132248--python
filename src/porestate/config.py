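"""Run configuration for the command-line pipeline.

Two formats are accepted: a flat ``key = value`` file using the historical
keyword spellings (``fn-trr``, ``pore-axis-basis-from``,
``pore-axis-basis-to``, ``site-boundary``, ``site-max-radius``, ...; a
leading ``--`` on a key is tolerated) and YAML with the same keys.  CLI
flags override config-file values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Unknown or invalid configuration key/value."""


@dataclass
class RunConfig:
    fn_trr: list[str] = field(default_factory=list)
    fn_topology: str | None = None
    trajectory_format: str = "plaintext"
    pore_axis_basis_from: str | None = None
    pore_axis_basis_to: str | None = None
    ion_selection: str | None = None
    species_label: str = "K"
    site_boundary: list[float] = field(default_factory=list)
    site_max_radius: float = float("inf")
    bin_width: float = 0.25
    gap_score: float = 0.0
    normalize_similarity: bool = True
    linkage: str = "average"
    min_offsite_frames: int = 1
    include_trailing_partial: bool = False
    output_dir: str = "porestate_out"
    seed: int = 0
    base_dir: str = "."  # directory config paths are resolved against

    def resolve(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else Path(self.base_dir) / q

    def sha256(self) -> str:
        payload = {
            f.name: getattr(self, f.name) for f in fields(self) if f.name != "base_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_LIST_KEYS = {"fn_trr"}
_FLOAT_LIST_KEYS = {"site_boundary"}
_BOOL_KEYS = {"normalize_similarity", "include_trailing_partial"}
_INT_KEYS = {"seed", "min_offsite_frames"}
_FLOAT_KEYS = {"site_max_radius", "bin_width", "gap_score"}


def _normalize_key(key: str) -> str:
    return key.strip().lstrip("-").replace("-", "_")


def _split_list(value) -> list[str]:
    if isinstance(value, (list, tuple)):
        return [str(v) for v in value]
    return [v for v in str(value).replace(",", " ").split() if v]


def _coerce(key: str, value) -> object:
    if key in _LIST_KEYS:
        return _split_list(value)
    if key in _FLOAT_LIST_KEYS:
        try:
            return [float(v) for v in _split_list(value)]
        except ValueError as exc:
            raise ConfigError(f"key {key!r}: non-numeric boundary in {value!r}") from exc
    if key in _BOOL_KEYS:
        if isinstance(value, bool):
            return value
        s = str(value).strip().lower()
        if s in ("1", "true", "yes", "on"):
            return True
        if s in ("0", "false", "no", "off"):
            return False
        raise ConfigError(f"key {key!r}: expected a boolean, got {value!r}")
    try:
        if key in _INT_KEYS:
            return int(value)
        if key in _FLOAT_KEYS:
            return float(value)
    except ValueError as exc:
        raise ConfigError(f"key {key!r}: bad numeric value {value!r}") from exc
    return str(value)


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat key=value or YAML config file into a :class:`RunConfig`."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw: dict[str, object] = {}
    if path.suffix in (".yaml", ".yml"):
        loaded = yaml.safe_load(path.read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: YAML config must be a mapping")
        raw = {str(k): v for k, v in loaded.items()}
    else:
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
    return build_config(raw, base_dir=str(path.parent))


def build_config(raw: dict[str, object], base_dir: str = ".") -> RunConfig:
    known = {f.name for f in fields(RunConfig)}
    cfg = RunConfig(base_dir=base_dir)
    for key, value in raw.items():
        norm = _normalize_key(key)
        if norm not in known or norm == "base_dir":
            raise ConfigError(f"unknown configuration key {key!r}")
        setattr(cfg, norm, _coerce(norm, value))
    if cfg.site_boundary and any(
        hi <= lo for hi, lo in zip(cfg.site_boundary, cfg.site_boundary[1:])
    ):
        cfg.site_boundary = sorted(cfg.site_boundary, reverse=True)
    if cfg.site_max_radius is not None and not cfg.site_max_radius > 0:
        raise ConfigError("site-max-radius must be positive")
    return cfg
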