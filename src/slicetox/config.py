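"""Run configuration: YAML loading, validation, defaults.

Validation aggregates every offense into a single ConfigError so a user
fixes one round of problems, not one problem per round.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

DEFAULT_EDGES = [float(e) for e in range(0, 301, 30)]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; see validate_config for the YAML surface."""

    # Input: either a synthetic preset or a pair of TIFF paths.
    preset: str | None = "fig1"
    green_path: str | None = None
    red_path: str | None = None
    channels: list = field(default_factory=lambda: ["green", "red"])
    seed: int = 0
    # Geometry (used when reading TIFFs; presets carry their own).
    pixel_size: float = 1.2
    z_step: float = 3.0
    # Preprocessing.
    group_size: int = 5
    smooth_radius: int = 2
    eight_bit: bool = True
    joint_scale: bool = True
    # Detection.
    threshold_k: float = 5.0
    red_filter: list = field(default_factory=lambda: [10.0, 100.0, 0.5, 1.0])
    green_filter: list = field(default_factory=lambda: [20.0, 200.0, 0.5, 1.0])
    dedup_radius: float = 10.0
    # Ratiometric elimination.
    ratio_convention: str = "excess"
    ratio_threshold: float = -0.4
    ratio_refit: bool = False
    # Colocalization.
    match_radius: float = 10.0
    max_mip_gap: int = 1
    # Depth profiling.
    edges: list = field(default_factory=lambda: list(DEFAULT_EDGES))
    # Synthetic overrides applied on top of the preset.
    synthetic: dict = field(default_factory=dict)
    # Output.
    out_dir: str = "slicetox_out"
    log_level: str = "INFO"


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def _validate(cfg: RunConfig) -> list[str]:
    errs = []
    if cfg.preset is None:
        if not cfg.green_path or not cfg.red_path:
            errs.append("input: need either a preset or both green_path and red_path")
        else:
            for key in ("green_path", "red_path"):
                p = getattr(cfg, key)
                if not Path(p).exists():
                    errs.append(f"{key}: file not found: {p}")
    if cfg.pixel_size <= 0:
        errs.append("pixel_size: must be > 0")
    if cfg.z_step <= 0:
        errs.append("z_step: must be > 0")
    if cfg.group_size < 1:
        errs.append("group_size: must be >= 1")
    if cfg.smooth_radius < 0:
        errs.append("smooth_radius: must be >= 0")
    if cfg.threshold_k <= 0:
        errs.append("threshold.k: must be > 0")
    for name in ("red_filter", "green_filter"):
        f = getattr(cfg, name)
        if len(f) != 4:
            errs.append(f"{name}: expected [size_min, size_max, circ_min, circ_max]")
        elif not (f[0] < f[1] and 0 <= f[2] <= f[3] <= 1):
            errs.append(f"{name}: size_min < size_max and 0 <= circ_min <= circ_max <= 1 required")
    if cfg.ratio_convention not in ("excess", "symmetric"):
        errs.append("ratio_convention: must be 'excess' or 'symmetric'")
    if cfg.match_radius < 0:
        errs.append("match_radius: must be >= 0")
    if cfg.max_mip_gap < 0:
        errs.append("max_mip_gap: must be >= 0")
    edges = np.asarray(cfg.edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        errs.append("edges: must be ascending with at least two values")
    return errs


def normalize_config(data: dict) -> RunConfig:
    """Apply defaults, check keys and ranges; raise ConfigError listing every offense."""
    errs = [f"unknown key: {k}" for k in data if k not in _KNOWN_KEYS]
    known = {k: v for k, v in data.items() if k in _KNOWN_KEYS}
    cfg = RunConfig(**known)
    errs += _validate(cfg)
    if errs:
        raise ConfigError(errs)
    return cfg


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(["configuration root must be a mapping"])
    return normalize_config(data)


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
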