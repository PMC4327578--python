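"""Run configuration: one model source plus ensemble/stop/sink settings.

Configs come from TOML or YAML key-value files; CLI flags override file
values, which override defaults.
"""

from __future__ import annotations

import os
import tomllib
from dataclasses import dataclass, fields

import yaml

__all__ = ["RunConfig", "load_config_file"]


@dataclass
class RunConfig:
    sbml: str | None = None
    factory: str | None = None  # "decay-dimer" or "gene-battery"
    k: int = 4  # gene-battery units
    n: int = 1
    seed: int = 0
    max_steps: int | None = None
    max_time: float | None = None
    cadence: int = 1
    n_ways: int = 1
    buffer_capacity: int = 1024
    sink: str = "memory"
    log_level: str = "INFO"

    def validate(self) -> list[str]:
        problems = []
        if (self.sbml is None) == (self.factory is None):
            problems.append("exactly one model source required: --sbml or --factory")
        if self.factory is not None and self.factory not in ("decay-dimer", "gene-battery"):
            problems.append(f"unknown factory model {self.factory!r}")
        if self.n < 1:
            problems.append("n must be >= 1")
        if self.k < 1:
            problems.append("k must be >= 1")
        if self.max_steps is None and self.max_time is None:
            problems.append("need a stop criterion: --steps and/or --time")
        if self.max_steps is not None and self.max_steps < 0:
            problems.append("steps must be >= 0")
        if self.max_time is not None and self.max_time < 0:
            problems.append("time must be >= 0")
        if self.cadence < 1:
            problems.append("cadence must be >= 1")
        if self.n_ways < 1:
            problems.append("n-ways must be >= 1")
        if self.buffer_capacity < 1:
            problems.append("buffer capacity must be >= 1")
        return problems


def load_config_file(path: str) -> dict:
    """Read a TOML or YAML config into a flat key-value dict."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path!r} must be a key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return data
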