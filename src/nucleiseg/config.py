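"""Pipeline configuration: every tunable of the segmentation chain in one
validated, hashable record.

Defaults correspond to 40x magnification H&E tiles (~0.25 um/pixel): a
radius-7 disk for the reconstruction filters, a radius-3 disk for binary
boundary smoothing, and h = 3 px for the H-maxima internal markers.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a configuration file."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the nuclei-extraction pipeline.

    Parameters
    ----------
    se_radius_preproc : int
        Disk radius (px) for opening/closing by reconstruction.  Should be
        of the order of the nucleus radius; results are insensitive below ~8
        at 40x.
    se_radius_smooth : int
        Disk radius (px) for binary opening of the threshold mask.
    hmax_h : float
        Dynamic threshold h (px) of the H-maxima transform on the distance
        map.  Small values keep small nuclei; clump separation is handled by
        the refinement stage, not by h.
    min_area : int
        Minimum object area (px) kept after watershed; removes debris.
    n_bins : int
        Histogram bins for Otsu thresholding.
    stain : {"auto", "ruifrok"}
        "auto" estimates the stain matrix from the image (SVD-plane method,
        falling back to the published Ruifrok-Johnston H&E vectors on
        near-white images); "ruifrok" always uses the published vectors.
    background_intensity : float
        Unstained transmission intensity I0 for the optical-density
        transform.
    external_marker_radius : int
        Disk radius (px) of the erosion producing per-region external
        markers during refinement.
    max_n : int
        Cap on regional maxima per region in refinement; bounds the number
        of candidate watersheds evaluated on irregular regions.
    kmeans_max_iter : int
        Lloyd-iteration cap for maxima clustering.
    min_hema_od : float
        Minimum 99th-percentile hematoxylin absorbance (OD units) for a
        tile to be considered to contain nuclei at all; below it the
        pipeline returns an empty segmentation instead of thresholding
        noise.
    min_iou : float
        IoU at or above which a predicted object counts as matching a
        ground-truth nucleus in evaluation.
    min_frac : float
        Fraction of a ground-truth nucleus a predicted object must cover to
        count as one of its covering objects in split-error evaluation.
    rng_seed : int
        Seed for any stochastic mode (the default pipeline is fully
        deterministic).
    """

    se_radius_preproc: int = 7
    se_radius_smooth: int = 3
    hmax_h: float = 3.0
    min_area: int = 30
    n_bins: int = 256
    stain: str = "auto"
    background_intensity: float = 255.0
    min_hema_od: float = 0.2
    external_marker_radius: int = 3
    max_n: int = 12
    kmeans_max_iter: int = 100
    tie_break: str = "smallest_k"
    min_iou: float = 0.5
    min_frac: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.se_radius_preproc < 1 or self.se_radius_smooth < 1:
            raise ConfigError("structuring-element radii must be >= 1")
        if self.hmax_h <= 0:
            raise ConfigError("hmax_h must be positive")
        if self.min_area < 0:
            raise ConfigError("min_area must be >= 0")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if self.stain not in ("auto", "ruifrok"):
            raise ConfigError(f"unknown stain mode {self.stain!r}")
        if self.background_intensity <= 0:
            raise ConfigError("background_intensity must be positive")
        if not 0 < self.min_iou < 1:
            raise ConfigError("min_iou must lie in (0, 1)")
        if self.tie_break != "smallest_k":
            raise ConfigError(f"unknown tie_break {self.tie_break!r}")
        if self.max_n < 1:
            raise ConfigError("max_n must be >= 1")

    def fixed_stain_matrix(self):
        from .stains import RUIFROK_HE

        return RUIFROK_HE

    # ---- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the effective parameters (changes iff any does)."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
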