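"""Run configuration: a small, fully validated YAML key-value file."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class CompareConfig:
    min_ir: int = 1000
    max_mismatch_frac: float = 0.01
    drop_ir: str = "IRb"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    rank_metric: str = "sv"
    top_n: int = 10
    reference: str | None = None
    seed: int = 0


_TYPES = {f.name: f.type for f in fields(CompareConfig)}


def load_config(path: str | Path | None) -> CompareConfig:
    """Parse and validate a config file; defaults fill missing keys,
    unknown keys and type mismatches are rejected with every offending
    key named."""
    if path is None:
        return CompareConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a key: value mapping")
    problems = []
    known = {f.name: f for f in fields(CompareConfig)}
    clean = {}
    for key, val in raw.items():
        if key not in known:
            problems.append(f"unknown key {key!r}")
            continue
        default = getattr(CompareConfig(), key)
        if default is None or isinstance(default, str):
            ok = isinstance(val, str) or val is None
        elif isinstance(default, bool):
            ok = isinstance(val, bool)
        elif isinstance(default, int) and not isinstance(default, bool):
            ok = isinstance(val, int) and not isinstance(val, bool)
        else:
            ok = isinstance(val, (int, float)) and not isinstance(val, bool)
        if not ok:
            problems.append(f"bad type for {key!r}: {val!r}")
        else:
            clean[key] = val
    if problems:
        raise ConfigError("; ".join(problems))
    return CompareConfig(**clean)


def effective_config(cfg: CompareConfig) -> dict:
    return asdict(cfg)
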