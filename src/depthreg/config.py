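"""Benchmark configuration: schema, validation, YAML I/O.

Unknown keys are rejected so a typo can never silently fall back to a
tolerance default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

from .exceptions import ConfigError
from .simulator import TrackingNoise

__all__ = ["BenchmarkConfig", "load_config", "save_config"]


@dataclass
class BenchmarkConfig:
    """Everything that defines one benchmark run.

    Protocol defaults mirror the evaluation protocol: 10 positions with 5
    captures each in both the registration and the testing phase, a 95%
    overlap exclusion gate, 5 mm overlap distance tolerance (equal to the
    registration voxel size) and a 10 mm margin around the craniotomy
    bounding box.
    """

    preset: str = "d405"
    algorithm: str = "icp"
    seed: int = 0
    n_positions: int = 10
    n_captures: int = 5
    overlap_threshold: float = 0.95
    dist_tol_mm: float = 5.0
    voxel_mm: float = 5.0
    roi_margin_mm: float = 10.0
    phantom_spacing_mm: float = 2.0
    tracking_rot_sigma_deg: float = 0.05
    tracking_trans_sigma_mm: float = 0.15
    registration_standoff_mm: float = 442.0
    testing_standoff_mm: float = 454.0
    coregister: bool = False
    axial_sigma_override_mm: float | None = None

    def __post_init__(self):
        if not (0.0 < self.overlap_threshold <= 1.0):
            raise ConfigError("overlap_threshold must be in (0, 1]")
        for name in ("dist_tol_mm", "voxel_mm", "roi_margin_mm", "phantom_spacing_mm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_positions < 1 or self.n_captures < 1:
            raise ConfigError("protocol counts must be >= 1")
        if self.tracking_rot_sigma_deg < 0 or self.tracking_trans_sigma_mm < 0:
            raise ConfigError("tracking noise must be non-negative")

    @property
    def tracking_noise(self) -> TrackingNoise:
        return TrackingNoise(self.tracking_rot_sigma_deg, self.tracking_trans_sigma_mm)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path, overrides: dict | None = None) -> BenchmarkConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ConfigError(f"config {path} must be a mapping")
    known = {f.name for f in fields(BenchmarkConfig)}
    unknown = sorted(set(d) - known)
    if unknown:
        raise ConfigError(f"unknown config keys {unknown}; known keys: {sorted(known)}")
    if overrides:
        d.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return BenchmarkConfig(**d)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(path, config: BenchmarkConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
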