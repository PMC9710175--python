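"""Structured run configuration: YAML in, validated dataclasses out.

A config file has up to four blocks (``model``, ``synth``, ``pipeline``,
``stats``) plus global keys ``rng_seed``, ``out_dir`` and ``log_level``.
Unknown keys are rejected and out-of-range values raise with the offending
field named, so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .lattice import ModelConfig
from .synthetic import SyntheticParams
from .tradeoff import TradeoffParams

__all__ = ["RunConfig", "PipelineOptions", "StatsOptions",
           "load_config", "save_config", "write_metadata"]


@dataclass(frozen=True)
class PipelineOptions:
    k_sigma: float = 3.0
    background_radius: int = 25
    control: str = "first_frame"

    def __post_init__(self) -> None:
        if self.k_sigma < 0:
            raise ValueError("pipeline.k_sigma must be >= 0")
        if self.background_radius < 1:
            raise ValueError("pipeline.background_radius must be >= 1")


@dataclass(frozen=True)
class StatsOptions:
    bins_state_map: int = 50
    bins_trajectory: int = 40
    bic_margin: float = 10.0
    window_start_min: float = 0.0

    def __post_init__(self) -> None:
        if self.bins_state_map < 2 or self.bins_trajectory < 2:
            raise ValueError("stats bin counts must be >= 2")


@dataclass
class RunConfig:
    """Fully resolved configuration of one run."""

    params: TradeoffParams = field(default_factory=TradeoffParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    synth: SyntheticParams = field(default_factory=SyntheticParams)
    pipeline: PipelineOptions = field(default_factory=PipelineOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)
    rng_seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "params": dataclasses.asdict(self.params),
            "model": dataclasses.asdict(self.model),
            "synth": dataclasses.asdict(self.synth),
            "pipeline": dataclasses.asdict(self.pipeline),
            "stats": dataclasses.asdict(self.stats),
            "rng_seed": self.rng_seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }


_BLOCKS = {
    "params": TradeoffParams,
    "model": ModelConfig,
    "synth": SyntheticParams,
    "pipeline": PipelineOptions,
    "stats": StatsOptions,
}
_GLOBALS = {"rng_seed": int, "out_dir": str, "log_level": str}


def _build_block(cls, block: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in '{name}' block: {sorted(unknown)}")
    try:
        return cls(**block)
    except ValueError as err:
        raise ValueError(f"invalid value in '{name}' block: {err}") from err


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; missing blocks and keys fall back to defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping at top level")
        raw = loaded
    if overrides:
        for key, block in overrides.items():
            if isinstance(block, dict):
                raw.setdefault(key, {}).update(
                    {k: v for k, v in block.items() if v is not None})
            elif block is not None:
                raw[key] = block

    unknown = set(raw) - set(_BLOCKS) - set(_GLOBALS)
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")

    kwargs = {}
    for name, cls in _BLOCKS.items():
        kwargs[name] = _build_block(cls, raw.get(name, {}) or {}, name)
    for name, cast in _GLOBALS.items():
        if name in raw:
            kwargs[name] = cast(raw[name])
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_metadata(path: str | Path, config: RunConfig, **extra) -> None:
    """Record the fully resolved config + seed (+ anything extra) as JSON."""
    from . import __version__

    obj = {"package": "metapatch", "version": __version__,
           "config": config.to_dict()}
    obj.update(extra)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
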