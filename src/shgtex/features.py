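"""Patch extraction and the 352-dimensional per-patch texture descriptor.

An image is sampled on a regular square grid of 64x64-pixel patches.  Each
patch is partitioned into the 8x8 grid of 8x8-pixel ROIs, the GLCM texture
parameters are evaluated per ROI and per orientation, and each
(parameter, orientation) set of 64 ROI values is histogrammed into 22
fixed-range bins.  Concatenating the histograms of correlation, ASM,
contrast and IDM over the four orientations gives the descriptor

    V = (h_Cor, h_ASM, h_Con, h_IDM),   h = (h_0, h_45, h_90, h_135)

of length 4 * 4 * 22 = 352.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import FeatureConfig, GLCMConfig
from .errors import ShapeError
from .glcm import PARAM_NAMES, THETAS, glcm_stack, patch_roi_blocks, quantize_levels, texture_params_stack

__all__ = [
    "BOF_PARAMS",
    "N_BINS",
    "Patch",
    "param_range",
    "extract_patches",
    "filter_signal_patches",
    "patch_feature_vector",
    "full_texture_profile",
    "image_feature_matrix",
]

#: Parameters entering the BoF descriptor, in layout order.
BOF_PARAMS: tuple[str, ...] = ("correlation", "asm", "contrast", "idm")

N_BINS = 22
FEATURE_DIM = len(BOF_PARAMS) * len(THETAS) * N_BINS  # 352


@dataclass(frozen=True)
class Patch:
    """A grid-located square crop of a parent image."""

    pixels: np.ndarray
    origin: tuple[int, int]
    parent_id: str | None = None


def param_range(name: str, levels: int) -> tuple[float, float]:
    """Theoretical support of a texture parameter for an N-level GLCM.

    Fixed, data-independent histogram ranges keep descriptors comparable
    across patches and images.
    """
    n = levels
    ranges = {
        "correlation": (-1.0, 1.0),
        "asm": (0.0, 1.0),
        "contrast": (0.0, float((n - 1) ** 2)),
        "idm": (0.0, 1.0),
        "entropy": (0.0, 2.0 * math.log(n)),
        "sum_entropy": (0.0, math.log(2 * n - 1)),
        "sum_average": (0.0, float(2 * n - 2)),
        "sum_variance": (0.0, (2 * n - 2) ** 2 / 4.0),
    }
    return ranges[name]


def extract_patches(
    image, patch_size: int = 64, grid_step: int = 64
) -> list[Patch]:
    """Crop all whole patches whose origins lie on the (grid_step) lattice.

    Origins are (a*g, b*g); partial border patches are dropped.  Patches are
    returned in row-major order.  An image smaller than the patch yields an
    empty list.
    """
    pixels = np.asarray(getattr(image, "pixels", image))
    image_id = getattr(image, "image_id", None)
    h, w = pixels.shape
    patches: list[Patch] = []
    for r in range(0, h - patch_size + 1, grid_step):
        for c in range(0, w - patch_size + 1, grid_step):
            patches.append(
                Patch(pixels[r : r + patch_size, c : c + patch_size], (r, c), image_id)
            )
    return patches


def filter_signal_patches(
    patches: list[Patch], threshold: int = 10, min_fraction: float = 0.25
) -> list[Patch]:
    """Keep patches whose fraction of pixels above ``threshold`` is >= ``min_fraction``."""
    kept = []
    for p in patches:
        frac = float(np.mean(p.pixels > threshold))
        if frac >= min_fraction:
            kept.append(p)
    return kept


def _roi_param_values(
    pixels: np.ndarray, cfg: GLCMConfig, params: tuple[str, ...]
) -> dict[tuple[str, int], np.ndarray]:
    """ROI-wise parameter values for each (parameter, theta) of a 64x64 patch."""
    if pixels.shape != (64, 64):
        raise ShapeError(f"expected a 64x64 patch, got {pixels.shape}")
    q = quantize_levels(pixels, cfg.levels)
    blocks = patch_roi_blocks(q, 8)
    cols = [PARAM_NAMES.index(p) for p in params]
    out: dict[tuple[str, int], np.ndarray] = {}
    for theta in THETAS:
        stack = glcm_stack(blocks, d=cfg.d, theta=theta, levels=cfg.levels, symmetric=cfg.symmetric)
        table = texture_params_stack(stack)
        for name, col in zip(params, cols):
            out[(name, theta)] = table[:, col]
    return out


def _histogram(values: np.ndarray, rng: tuple[float, float], n_bins: int) -> np.ndarray:
    counts, _ = np.histogram(values, bins=n_bins, range=rng)
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def patch_feature_vector(patch, cfg: GLCMConfig | None = None, n_bins: int = N_BINS) -> np.ndarray:
    """The 352-element texture descriptor of one 64x64 patch.

    Layout is parameter-major (Cor, ASM, Con, IDM), then orientation
    (0, 45, 90, 135 degrees), then bin; every 22-bin block is normalized to
    sum 1.  Deterministic: repeated calls yield identical vectors.
    """
    cfg = cfg or GLCMConfig()
    pixels = np.asarray(getattr(patch, "pixels", patch))
    values = _roi_param_values(pixels, cfg, BOF_PARAMS)
    blocks = [
        _histogram(values[(name, theta)], param_range(name, cfg.levels), n_bins)
        for name in BOF_PARAMS
        for theta in THETAS
    ]
    return np.concatenate(blocks)


def full_texture_profile(
    patch, cfg: GLCMConfig | None = None, n_bins: int = N_BINS
) -> dict[str, dict[int, np.ndarray]]:
    """Per-orientation histograms of all eight texture parameters.

    Exploratory companion to :func:`patch_feature_vector`; the classifier
    descriptor uses only the four parameters in :data:`BOF_PARAMS`.
    """
    cfg = cfg or GLCMConfig()
    pixels = np.asarray(getattr(patch, "pixels", patch))
    values = _roi_param_values(pixels, cfg, PARAM_NAMES)
    return {
        name: {
            theta: _histogram(values[(name, theta)], param_range(name, cfg.levels), n_bins)
            for theta in THETAS
        }
        for name in PARAM_NAMES
    }


def image_feature_matrix(image, cfg: FeatureConfig | None = None):
    """Descriptors of every signal patch of an image.

    Returns
    -------
    features : (n_patches, 352) float array (possibly empty).
    origins : list of (row, col) patch origins, aligned with rows.
    """
    cfg = cfg or FeatureConfig()
    patches = extract_patches(image, cfg.patch_size, cfg.grid_step)
    patches = filter_signal_patches(patches, cfg.signal_threshold, cfg.min_signal_fraction)
    if not patches:
        return np.empty((0, FEATURE_DIM)), []
    feats = np.stack([patch_feature_vector(p, cfg.glcm, cfg.n_bins) for p in patches])
    return feats, [p.origin for p in patches]
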