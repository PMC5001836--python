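"""Pipeline configuration: validated, hashable, YAML-loadable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold and geometry parameter of the pipeline in one place.

    Unknown keys are rejected on load; the config hash is embedded in every
    output file's provenance header.
    """

    seed: int

    # screen design / simulation
    n_plates: int = 2
    plate_rows: int = 16
    plate_cols: int = 24
    n_control_wells_per_class: int = 12
    baseline_ratio: float = 2.0
    positive_control_shift: float = -1.2
    negative_control_sd: float | None = None
    positive_control_sd: float | None = None
    row_slope: float = 0.0
    col_slope: float = 0.0
    noise_sd: float = 0.05
    planted_hits: dict[str, float] = field(default_factory=dict)
    decoy_hits: dict[str, float] = field(default_factory=dict)
    hit_active_sirnas: int = 4
    decoy_active_sirnas: int = 1
    hit_attenuation: float = 0.2
    decoy_attenuation: float = 1.0
    base_induction: float = 4.0
    qpcr_replicates: int = 3
    qpcr_noise_sd: float = 0.0
    secondary_noise_sd: float = 0.05
    secondary_cell_lines: tuple[str, ...] = ("HEK293A", "HT1080")

    # image quantification
    erosion_px: int = 2
    ring_width_px: int = 3
    gap_px: int = 0
    min_cells: int = 20
    min_area_px: int = 30
    threshold_method: str = "otsu"
    aggregation: str = "median"
    roi_metric: str = "euclidean"

    # normalization
    mad_scale: float = 1.4826
    xi_source: str = "residual"  # or "raw": skip positional-effect removal

    # hit selection
    primary_cutoff: float = -3.2
    secondary_min_hits: int = 2
    tertiary_max_ratio: float = 0.7

    def __post_init__(self) -> None:
        if self.plate_rows < 2 or self.plate_cols < 2:
            raise ConfigError("plate shape must be at least 2 x 2")
        if self.n_plates < 1:
            raise ConfigError("n_plates must be >= 1")
        for name in ("noise_sd", "secondary_noise_sd", "qpcr_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("erosion_px", "ring_width_px", "min_cells", "min_area_px"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.gap_px not in (0, 1):
            raise ConfigError("gap_px must be 0 or 1")
        if self.aggregation not in ("median", "mean", "pooled"):
            raise ConfigError("aggregation must be median, mean, or pooled")
        if self.roi_metric not in ("euclidean", "chessboard"):
            raise ConfigError("roi_metric must be euclidean or chessboard")
        if self.xi_source not in ("residual", "raw"):
            raise ConfigError("xi_source must be residual or raw")
        if self.mad_scale <= 0:
            raise ConfigError("mad_scale must be > 0")
        if self.secondary_min_hits < 1:
            raise ConfigError("secondary_min_hits must be >= 1")
        if not 0 < self.tertiary_max_ratio:
            raise ConfigError("tertiary_max_ratio must be > 0")
        if not 0 <= self.hit_attenuation <= 1 or not 0 <= self.decoy_attenuation <= 1:
            raise ConfigError("attenuation fractions must be in [0, 1]")
        object.__setattr__(self, "planted_hits", dict(self.planted_hits))
        object.__setattr__(self, "decoy_hits", dict(self.decoy_hits))
        object.__setattr__(self, "secondary_cell_lines", tuple(self.secondary_cell_lines))

    @property
    def plate_shape(self) -> tuple[int, int]:
        return (self.plate_rows, self.plate_cols)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ConfigError("config must set a seed")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["secondary_cell_lines"] = list(self.secondary_cell_lines)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
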