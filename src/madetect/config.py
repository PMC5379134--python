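"""Pipeline configuration.

A single :class:`PipelineConfig` carries every tunable of the detector, from
preprocessing through dictionary learning to evaluation, so that a trained
model can be persisted together with the exact settings that produced it.
Precedence when resolving a run is: explicit overrides (CLI flags) > config
file > built-in defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # multiscale correlation filtering
    sigma_min: float = 1.1
    sigma_max: float = 1.5
    sigma_step: float = 0.1
    correlation_threshold: float = 0.6
    # region growing
    beta: float = 0.5
    max_region_area: int = 120
    bg_mean_window: int = 25
    seed_dilation: int = 2
    grow_window_half: int = 40
    # patches / features
    patch_size: int = 11
    n_features: int = 8
    # fusion + dictionary learning
    fused_dim: int = 3
    atoms_per_subdictionary: int = 256
    omp_sparsity: int = 5
    ksvd_iterations: int = 15
    # preprocessing
    working_resolution: int = 850
    clahe_clip_limit: float = 0.01
    clahe_tiles: int = 8
    smoothing_sigma: float = 1.0
    smoothing_width: int = 5
    # vessel heuristic
    vessel_bottomhat_radius: int = 8
    vessel_threshold: float = 0.1
    vessel_min_area: int = 150
    vessel_min_eccentricity: float = 0.9
    # evaluation
    match_radius: float = 5.0
    # classification
    tie_break_label: int = 1
    # randomness
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.correlation_threshold < 1.0):
            raise ConfigError("correlation_threshold must lie in (0, 1)")
        if not (0.0 <= self.beta <= 1.0):
            raise ConfigError("beta must lie in [0, 1]")
        if self.patch_size % 2 != 1 or self.patch_size < 3:
            raise ConfigError("patch_size must be an odd integer >= 3")
        if self.fused_dim > self.n_features:
            raise ConfigError("fused_dim (M) must not exceed n_features (K)")
        if not (1 <= self.n_features <= 8):
            raise ConfigError("n_features must be between 1 and 8")
        if self.sigma_min > self.sigma_max or self.sigma_step <= 0:
            raise ConfigError("invalid sigma range")
        if self.omp_sparsity < 1:
            raise ConfigError("omp_sparsity must be >= 1")
        if self.match_radius < 0:
            raise ConfigError("match_radius must be nonnegative")

    @property
    def sigmas(self) -> tuple[float, ...]:
        """Strictly increasing Gaussian scales of the filter bank."""
        n = int(round((self.sigma_max - self.sigma_min) / self.sigma_step)) + 1
        return tuple(round(self.sigma_min + i * self.sigma_step, 10) for i in range(n))

    @property
    def patch_dim(self) -> int:
        """p = patch_size**2, the length of a vectorized patch."""
        return self.patch_size ** 2

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, values: Mapping[str, Any]) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(values))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **overrides: Any) -> "PipelineConfig":
        """New config with the given fields changed (None values are ignored)."""
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage generator split deterministically from the single seed."""
        ss = np.random.SeedSequence([self.rng_seed, _stage_key(stage)])
        return np.random.default_rng(ss)


def _stage_key(stage: str) -> int:
    # stable 31-bit hash of the stage name (Python's hash() is salted)
    h = 0
    for ch in stage.encode():
        h = (h * 131 + ch) % (2 ** 31 - 1)
    return h


def resolve_config(config_file: str | Path | None = None,
                   **overrides: Any) -> PipelineConfig:
    """Resolve a config with precedence: overrides > file > defaults."""
    cfg = PipelineConfig() if config_file is None else PipelineConfig.from_json(config_file)
    return cfg.replace(**overrides)
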