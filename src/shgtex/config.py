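"""Run configuration: dataclasses with every default explicit, YAML round-trip.

All tunables that the analysis depends on live here so that a single YAML
file fully determines a run.  ``config_hash`` gives a stable digest used to
stamp persisted model bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidParameterError

__all__ = [
    "GLCMConfig",
    "FeatureConfig",
    "BoFConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
]


@dataclass(frozen=True)
class GLCMConfig:
    """Co-occurrence matrix settings.

    levels : gray-level quantization applied to each ROI before counting.
    d : pixel pair offset distance.
    symmetric : count each pair in both directions (p becomes symmetric).
    """

    levels: int = 8
    d: int = 1
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise InvalidParameterError(f"levels must be >= 2, got {self.levels}")
        if self.d < 1:
            raise InvalidParameterError(f"d must be >= 1, got {self.d}")


@dataclass(frozen=True)
class FeatureConfig:
    """Patch extraction and descriptor settings."""

    patch_size: int = 64
    grid_step: int = 64
    roi_size: int = 8
    n_bins: int = 22
    signal_threshold: int = 10
    min_signal_fraction: float = 0.25
    glcm: GLCMConfig = field(default_factory=GLCMConfig)

    def __post_init__(self) -> None:
        if self.patch_size % self.roi_size != 0:
            raise InvalidParameterError(
                f"patch_size {self.patch_size} not divisible by roi_size {self.roi_size}"
            )
        if self.grid_step < 1:
            raise InvalidParameterError("grid_step must be positive")
        if not 0.0 < self.min_signal_fraction <= 1.0:
            raise InvalidParameterError("min_signal_fraction must be in (0, 1]")


@dataclass(frozen=True)
class BoFConfig:
    """Codebook / classifier settings.

    vocabulary_mode: "strict" builds the codebook from training-fold images
    only; "paper" builds it from all images of the set.
    """

    k: int = 20
    n_runs: int = 4
    vocabulary_mode: str = "strict"
    svm_c: float = 1.0
    kmeans_restarts: int = 10

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InvalidParameterError("codebook size k must be >= 2")
        if self.vocabulary_mode not in ("strict", "paper"):
            raise InvalidParameterError(
                f"vocabulary_mode must be 'strict' or 'paper', got {self.vocabulary_mode!r}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for a full pipeline run."""

    feature: FeatureConfig = field(default_factory=FeatureConfig)
    bof: BoFConfig = field(default_factory=BoFConfig)
    # whole-image signal filter (strictly-greater-than rule)
    image_signal_threshold: int = 10
    image_min_signal_fraction: float = 0.25
    seed: int = 0


def _to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def _from_dict(data: dict) -> RunConfig:
    feature = data.get("feature", {})
    glcm = GLCMConfig(**feature.pop("glcm", {})) if isinstance(feature, dict) else GLCMConfig()
    fc = FeatureConfig(glcm=glcm, **feature)
    bc = BoFConfig(**data.get("bof", {}))
    extra = {
        k: data[k]
        for k in ("image_signal_threshold", "image_min_signal_fraction", "seed")
        if k in data
    }
    return RunConfig(feature=fc, bof=bc, **extra)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file; absent keys keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 digest of the full configuration."""
    canon = json.dumps(_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
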