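"""Image containers, bit-depth conversion, cropping and whole-image filtering.

Coordinate convention: (row, col), 0-based, top-left origin, half-open crop
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import RangeError, ShapeError

__all__ = [
    "GrayImage",
    "LabeledImageSet",
    "convert_12_to_8bit",
    "crop_subimages",
    "filter_signal_images",
    "read_image",
    "write_image",
    "load_manifest",
]


@dataclass(frozen=True)
class GrayImage:
    """8-bit grayscale image with acquisition metadata."""

    pixels: np.ndarray
    pixel_size_um: float = 0.25
    source_bit_depth: int = 8
    image_id: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ShapeError(f"image must be 2-D, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise RangeError("8-bit image values must lie in [0, 255]")
            object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabeledImageSet:
    """Images with one category label each."""

    images: list[GrayImage]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ShapeError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))


def convert_12_to_8bit(
    raw: np.ndarray,
    pixel_size_um: float = 0.25,
    image_id: str | None = None,
    rescale_percentiles: tuple[float, float] | None = None,
) -> GrayImage:
    """Convert a 12-bit recording to the 8-bit image the analysis runs on.

    Default is the order-preserving floor(v / 16).  The optional
    percentile-rescale mode maps [p_lo, p_hi] linearly onto [0, 255] and is
    off by default.
    """
    raw = np.asarray(raw)
    if raw.min() < 0 or raw.max() > 4095:
        raise RangeError("12-bit values must lie in [0, 4095]")
    if rescale_percentiles is None:
        out = (raw.astype(np.int64) // 16).astype(np.uint8)
    else:
        lo, hi = np.percentile(raw, rescale_percentiles)
        span = max(hi - lo, 1.0)
        out = np.clip((raw - lo) / span * 255.0, 0, 255).astype(np.uint8)
    return GrayImage(out, pixel_size_um=pixel_size_um, source_bit_depth=12, image_id=image_id)


def crop_subimages(
    image: GrayImage,
    size: int = 512,
    mode: str = "regular_blocks",
    rois: list[tuple[int, int]] | None = None,
) -> list[GrayImage]:
    """Cut an acquisition into ``size`` x ``size`` analysis sub-images.

    ``regular_blocks`` tiles the image exactly (dimensions must divide);
    ``manual_rois`` crops at the given (row, col) origins, rejecting any ROI
    that extends outside the image (no resampling).
    """
    h, w = image.shape
    base = image.image_id or "image"
    crops: list[GrayImage] = []
    if mode == "regular_blocks":
        if h % size or w % size:
            raise ShapeError(f"image shape {image.shape} not divisible by block size {size}")
        for r in range(0, h, size):
            for c in range(0, w, size):
                crops.append(
                    replace(
                        image,
                        pixels=image.pixels[r : r + size, c : c + size],
                        image_id=f"{base}_r{r}_c{c}",
                    )
                )
    elif mode == "manual_rois":
        if rois is None:
            raise ShapeError("manual_rois mode requires a list of (row, col) origins")
        for r, c in rois:
            if r < 0 or c < 0 or r + size > h or c + size > w:
                raise ShapeError(f"ROI at ({r}, {c}) size {size} extends outside {image.shape}")
            crops.append(
                replace(
                    image,
                    pixels=image.pixels[r : r + size, c : c + size],
                    image_id=f"{base}_r{r}_c{c}",
                )
            )
    else:
        raise ShapeError(f"unknown crop mode {mode!r}")
    return crops


def filter_signal_images(
    images: list[GrayImage], threshold: int = 10, min_fraction: float = 0.25
) -> list[GrayImage]:
    """Keep images whose signal area is strictly greater than ``min_fraction``.

    A pixel counts as signal when its gray level exceeds ``threshold``.  The
    whole-image rule is strict ("more than"), unlike the patch-level filter
    which is inclusive.
    """
    return [im for im in images if float(np.mean(im.pixels > threshold)) > min_fraction]


def read_image(path: str | Path, pixel_size_um: float = 0.25) -> GrayImage:
    """Read an 8-bit grayscale TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3:  # collapse accidental channel axis
        px = px[..., 0]
    return GrayImage(px.astype(np.uint8), pixel_size_um=pixel_size_um, image_id=path.stem)


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale TIFF or PNG; round-trips pixels exactly."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)


def load_manifest(path: str | Path, pixel_size_um: float = 0.25) -> LabeledImageSet:
    """Load a dataset from a CSV manifest with columns (filename, label).

    Filenames are resolved relative to the manifest location.
    """
    path = Path(path)
    table = pd.read_csv(path)
    images, labels = [], []
    for _, row in table.iterrows():
        images.append(read_image(path.parent / row["filename"], pixel_size_um))
        labels.append(str(row["label"]))
    return LabeledImageSet(images=images, labels=labels)
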