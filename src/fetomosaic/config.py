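"""Pipeline configuration: thresholds, backend choice, YAML round-trip.

The mosaicking literature this package follows fixes a handful of
operating-point constants — the dual-softmax confidence threshold
``theta_c`` (0.5), the keyframe discard fraction ``t_discard`` (10%) and the
keyframe feature-distance threshold ``t_kf`` (1300, a scale tied to the
feature backend). They live in a ``paper_defaults`` block of the YAML schema
so deviations from them are explicit in any config file.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["ConfigError", "PipelineConfig"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid configuration value or malformed config file."""


@dataclass
class PipelineConfig:
    """All tunables of the mosaicking + recovery pipeline.

    Attributes
    ----------
    backend:
        Name of the registered dense feature backend.
    tau:
        Softmax temperature of the coarse score matrix (> 0). Smaller values
        sharpen the dual-softmax confidences.
    theta_c:
        Confidence threshold for mutual-nearest-neighbour matches, in [0, 1].
    t_discard:
        New-keyframe trigger: fraction of the last keyframe's descriptors
        still matched in the current frame below which a keyframe is added.
    t_kf:
        Euclidean distance between pooled global features below which two
        consecutive keyframes are considered duplicates. Backend-scale
        dependent; ``global_scale`` calibrates the built-in backend to it.
    """

    # feature extraction / matching
    backend: str = "dense-grid"
    tau: float = 0.05
    fine_tau: float = 0.02
    theta_c: float = 0.5
    coarse_stride: int = 8
    fine_stride: int = 2
    refine_window: int = 5
    refine_min_peak: float = 0.25
    global_scale: float = 600000.0
    min_cell_cover: float = 0.5
    # RANSAC homography estimation
    ransac_threshold: float = 3.0
    ransac_max_iters: int = 2000
    ransac_confidence: float = 0.995
    ransac_seed: int = 0
    affine_fallback: bool = False
    guided_iters: int = 1
    patch_radius: int = 9
    patch_search: int = 3
    patch_iters: int = 2
    patch_min_corr: float = 0.5
    # tracking-loss criterion
    min_inliers: int = 10
    max_corner_disp_frac: float = 0.4
    # keyframes / relocalization
    t_discard: float = 0.10
    t_kf: float = 1300.0
    reloc_k: int = 3
    reloc_min_inliers: int = 10
    reloc_theta_c: float = 0.2
    # evaluation
    ssim_k: int = 5
    min_overlap_px: int = 1000

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.theta_c <= 1.0:
            raise ConfigError(f"theta_c must be in [0, 1], got {self.theta_c}")
        if self.tau <= 0 or self.fine_tau <= 0:
            raise ConfigError("temperatures tau and fine_tau must be positive")
        if not 0.0 < self.t_discard < 1.0:
            raise ConfigError(f"t_discard must be in (0, 1), got {self.t_discard}")
        if self.t_kf < 0:
            raise ConfigError("t_kf must be non-negative")
        if self.coarse_stride % self.fine_stride != 0:
            raise ConfigError("coarse_stride must be a multiple of fine_stride")
        if self.refine_window < 3 or self.refine_window % 2 == 0:
            raise ConfigError("refine_window must be odd and >= 3")
        if not 0.0 < self.ransac_confidence < 1.0:
            raise ConfigError("ransac_confidence must be in (0, 1)")
        if not 0.0 <= self.reloc_theta_c <= 1.0:
            raise ConfigError("reloc_theta_c must lie in [0, 1]")
        if self.min_inliers < 4 or self.reloc_min_inliers < 4:
            raise ConfigError("inlier minima must be >= 4 (homography d.o.f.)")
        if self.ssim_k < 0:
            raise ConfigError("ssim_k must be >= 0")

    # --- YAML schema -----------------------------------------------------
    _PAPER_KEYS = ("theta_c", "t_discard", "t_kf")

    def to_dict(self) -> dict:
        d = asdict(self)
        paper = {k: d.pop(k) for k in self._PAPER_KEYS}
        return {"schema_version": SCHEMA_VERSION, "paper_defaults": paper, **d}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported config schema version {version}")
        data.update(data.pop("paper_defaults", {}))
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
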