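"""Gray-level co-occurrence matrices and second-order texture parameters.

The co-occurrence matrix ``p(i, j)`` of a region gives the probability that
a pixel pair at offset distance ``d`` and orientation ``theta`` carries gray
levels ``i`` and ``j``.  Eight scalar parameters summarise it: correlation,
angular second moment (ASM), contrast, inverse difference moment (IDM),
entropy, sum entropy, sum average and sum variance.

Conventions (fixed once, used everywhere):

* coordinates are (row, col), 0-based, origin top-left;
* theta=0 pairs (r, c) with (r, c+d); theta=90 with (r-d, c);
  theta=45 with (r-d, c+d); theta=135 with (r-d, c-d);
* symmetric counting (both directions) is the default;
* logarithms are natural; 0*log(0) is taken as 0;
* entropies are returned as -sum(p log p) so they are non-negative;
* correlation is 0 when either marginal standard deviation vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .config import GLCMConfig
from .errors import EmptyPairError, InvalidParameterError, ShapeError

__all__ = [
    "THETAS",
    "PARAM_NAMES",
    "GLCMatrix",
    "TextureParams",
    "quantize_levels",
    "compute_glcm",
    "glcm_stack",
    "texture_params",
    "texture_params_stack",
    "patch_roi_blocks",
    "roi_param_map",
]

#: GLCM orientations in degrees, in the order used throughout the package.
THETAS: tuple[int, ...] = (0, 45, 90, 135)

#: Canonical parameter order of :func:`texture_params_stack` columns.
PARAM_NAMES: tuple[str, ...] = (
    "correlation",
    "asm",
    "contrast",
    "idm",
    "entropy",
    "sum_entropy",
    "sum_average",
    "sum_variance",
)

# (drow, dcol) per unit distance for each orientation
_OFFSETS: dict[int, tuple[int, int]] = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized co-occurrence matrix for one (d, theta)."""

    p: np.ndarray
    levels: int
    d: int
    theta: int
    symmetric: bool


@dataclass(frozen=True)
class TextureParams:
    correlation: float
    asm: float
    contrast: float
    idm: float
    entropy: float
    sum_entropy: float
    sum_average: float
    sum_variance: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])


def quantize_levels(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Linearly bin 8-bit gray values [0, 255] into ``levels`` equal bins.

    Bin edges sit at 256*k/levels with right-open bins, so the mapping is
    ``floor(v * levels / 256)``; order-preserving, 255 maps to the top bin.
    """
    if levels < 2:
        raise InvalidParameterError(f"levels must be >= 2, got {levels}")
    arr = np.asarray(pixels)
    return (arr.astype(np.int64) * levels) // 256


def _pair_views(q: np.ndarray, d: int, theta: int):
    """Return the two aligned views forming all in-bounds pairs at (d, theta).

    Works on a single 2-D region or on a stack (..., h, w); the offset is
    applied to the trailing two axes.
    """
    if theta not in _OFFSETS:
        raise InvalidParameterError(f"theta must be one of {THETAS}, got {theta}")
    dr, dc = (o * d for o in _OFFSETS[theta])
    # first pixel (r, c), second (r+dr, c+dc); dr <= 0 for all thetas here
    rows_a = slice(-dr, None) if dr else slice(None)
    rows_b = slice(None, dr) if dr else slice(None)
    if dc > 0:
        cols_a, cols_b = slice(None, -dc), slice(dc, None)
    elif dc < 0:
        cols_a, cols_b = slice(-dc, None), slice(None, dc)
    else:
        cols_a = cols_b = slice(None)
    a = q[..., rows_a, cols_a]
    b = q[..., rows_b, cols_b]
    return a, b


def compute_glcm(
    roi: np.ndarray,
    d: int = 1,
    theta: int = 0,
    levels: int = 8,
    symmetric: bool = True,
    prequantized: bool = False,
) -> GLCMatrix:
    """Co-occurrence probability matrix of a single region of interest.

    Pair counts at offset (d, theta) are divided by the total count; with
    ``symmetric`` each pair is counted in both directions and the matrix is
    exactly symmetric.

    Raises
    ------
    EmptyPairError
        If the region contains no pixel pair at the requested offset.
    """
    roi = np.asarray(roi)
    if roi.ndim != 2:
        raise ShapeError(f"ROI must be 2-D, got shape {roi.shape}")
    q = roi if prequantized else quantize_levels(roi, levels)
    a, b = _pair_views(q, d, theta)
    if a.size == 0:
        raise EmptyPairError(
            f"ROI of shape {roi.shape} has no pixel pairs at d={d}, theta={theta}"
        )
    counts = np.bincount(
        (a.ravel() * levels + b.ravel()), minlength=levels * levels
    ).reshape(levels, levels).astype(float)
    if symmetric:
        counts = counts + counts.T
    return GLCMatrix(
        p=counts / counts.sum(), levels=levels, d=d, theta=theta, symmetric=symmetric
    )


def glcm_stack(
    regions: np.ndarray,
    d: int = 1,
    theta: int = 0,
    levels: int = 8,
    symmetric: bool = True,
) -> np.ndarray:
    """Co-occurrence matrices of a stack of already-quantized regions.

    Parameters
    ----------
    regions : (m, h, w) integer array with values in [0, levels-1].

    Returns
    -------
    (m, levels, levels) array of normalized matrices, identical to calling
    :func:`compute_glcm` on each region with ``prequantized=True``.
    """
    regions = np.asarray(regions)
    m = regions.shape[0]
    a, b = _pair_views(regions, d, theta)
    if a.size == 0:
        raise EmptyPairError(
            f"regions of shape {regions.shape[1:]} have no pairs at d={d}, theta={theta}"
        )
    npairs = a.shape[1] * a.shape[2]
    roi_id = np.repeat(np.arange(m), npairs)
    flat = roi_id * (levels * levels) + a.reshape(m, -1).ravel() * levels + b.reshape(m, -1).ravel()
    counts = np.bincount(flat, minlength=m * levels * levels).astype(float)
    counts = counts.reshape(m, levels, levels)
    if symmetric:
        counts = counts + counts.transpose(0, 2, 1)
    return counts / counts.sum(axis=(1, 2), keepdims=True)


@lru_cache(maxsize=32)
def _diag_basis(n: int) -> np.ndarray:
    """One-hot matrix B of shape (n*n, 2n-1) with B[i*n+j, i+j] = 1."""
    idx = np.arange(n)
    s = (idx[:, None] + idx[None, :]).ravel()
    basis = np.zeros((n * n, 2 * n - 1))
    basis[np.arange(n * n), s] = 1.0
    return basis


def texture_params_stack(p: np.ndarray) -> np.ndarray:
    """Evaluate all eight texture parameters on a stack of GLCMs.

    Parameters
    ----------
    p : (m, n, n) stack of normalized co-occurrence matrices.

    Returns
    -------
    (m, 8) array; columns ordered as :data:`PARAM_NAMES`.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim == 2:
        p = p[None]
    m, n, _ = p.shape
    idx = np.arange(n, dtype=float)

    px = p.sum(axis=2)  # row marginal, (m, n)
    py = p.sum(axis=1)  # column marginal
    mu_i = px @ idx
    mu_j = py @ idx
    var_i = px @ idx**2 - mu_i**2
    var_j = py @ idx**2 - mu_j**2
    sigma = np.sqrt(np.clip(var_i, 0, None) * np.clip(var_j, 0, None))
    e_ij = np.einsum("mij,i,j->m", p, idx, idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        correlation = np.where(sigma > 0, (e_ij - mu_i * mu_j) / np.where(sigma > 0, sigma, 1.0), 0.0)

    asm = np.einsum("mij,mij->m", p, p)
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    contrast = np.einsum("mij,ij->m", p, diff2)
    inv_diff = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
    idm = np.einsum("mij,ij->m", p, inv_diff)

    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    entropy = -plogp.sum(axis=(1, 2))

    pxy = p.reshape(m, n * n) @ _diag_basis(n)  # (m, 2n-1)
    s_idx = np.arange(2 * n - 1, dtype=float)
    qlogq = np.where(pxy > 0, pxy * np.log(np.where(pxy > 0, pxy, 1.0)), 0.0)
    sum_entropy = -qlogq.sum(axis=1)
    sum_average = pxy @ s_idx
    sum_variance = ((s_idx[None, :] - sum_average[:, None]) ** 2 * pxy).sum(axis=1)

    return np.column_stack(
        [correlation, asm, contrast, idm, entropy, sum_entropy, sum_average, sum_variance]
    )


def texture_params(glcm: GLCMatrix | np.ndarray) -> TextureParams:
    """Eight texture parameters of a single normalized GLCM."""
    p = glcm.p if isinstance(glcm, GLCMatrix) else np.asarray(glcm)
    row = texture_params_stack(p[None] if p.ndim == 2 else p)[0]
    return TextureParams(*row)


def patch_roi_blocks(pixels: np.ndarray, roi_size: int = 8) -> np.ndarray:
    """Partition a square patch into its non-overlapping ROI blocks.

    Returns an (n_blocks, roi_size, roi_size) stack in row-major block order.
    """
    pixels = np.asarray(pixels)
    h, w = pixels.shape
    if h % roi_size or w % roi_size:
        raise ShapeError(
            f"patch shape {pixels.shape} not divisible by roi_size {roi_size}"
        )
    br, bc = h // roi_size, w // roi_size
    return (
        pixels.reshape(br, roi_size, bc, roi_size)
        .transpose(0, 2, 1, 3)
        .reshape(br * bc, roi_size, roi_size)
    )


def roi_param_map(
    patch: np.ndarray,
    parameter: str,
    theta: int,
    cfg: GLCMConfig | None = None,
) -> np.ndarray:
    """Map one texture parameter over the 8x8 ROI grid of a 64x64 patch.

    The value at grid cell (a, b) is the parameter of the GLCM of the
    8x8-pixel ROI at block position (a, b).
    """
    cfg = cfg or GLCMConfig()
    pixels = getattr(patch, "pixels", patch)
    pixels = np.asarray(pixels)
    if pixels.shape != (64, 64):
        raise ShapeError(f"expected a 64x64 patch, got {pixels.shape}")
    if parameter not in PARAM_NAMES:
        raise InvalidParameterError(f"unknown parameter {parameter!r}")
    q = quantize_levels(pixels, cfg.levels)
    blocks = patch_roi_blocks(q, 8)
    stack = glcm_stack(blocks, d=cfg.d, theta=theta, levels=cfg.levels, symmetric=cfg.symmetric)
    values = texture_params_stack(stack)[:, PARAM_NAMES.index(parameter)]
    return values.reshape(8, 8)
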