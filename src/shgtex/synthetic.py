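"""Labeled synthetic test images with tissue-like texture phenotypes.

Three generators emulate the morphologies the pipeline is built to
discriminate:

* cartilage-like: homogeneous moderate-intensity matrix punctured by dark
  circular lacunae on a jittered lattice (default pitch 60 px, i.e. 15 um
  at 0.25 um/px);
* bone-like: brighter matrix with anisotropic bright fiber streaks;
* fibrous-cartilage-like: cartilage base with a band of oriented thin
  fibers along the top surface.

Images are simulated at 12-bit depth and passed through the same
12-bit-to-8-bit conversion as acquired data.  Generation is deterministic:
the same (params, seed) yields byte-identical pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import InvalidParameterError
from .io import GrayImage, LabeledImageSet, convert_12_to_8bit, write_image

__all__ = [
    "TissueTextureParams",
    "gen_cartilage_image",
    "gen_bone_image",
    "gen_fibrous_image",
    "gen_dataset",
]


@dataclass(frozen=True)
class TissueTextureParams:
    """Geometry and intensity controls for one tissue class.

    Intensities are on the 8-bit scale; the simulation internally works at
    12-bit (value * 16) and converts down.
    """

    class_name: str = "Cartilage"
    base_intensity: float = 90.0
    noise_sd: float = 10.0
    lacuna_density: float = 2.8          # lacunae per 100x100 px; 0 disables
    lacuna_radius_range: tuple[float, float] = (8.0, 14.0)
    lacuna_spacing: float = 60.0         # lattice pitch, px (15 um at 0.25 um/px)
    fiber_count: int = 0
    fiber_width_px: float = 2.5
    fiber_gain: float = 55.0             # per-fiber peak brightness, 8-bit scale
    fiber_orientation: float | None = None   # radians; None draws one per image
    fiber_orientation_spread: float = 0.5    # radians
    surface_band_fraction: float = 0.25  # fibrous class: fiber band height / image height
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.base_intensity <= 255:
            raise InvalidParameterError("base_intensity must lie in [0, 255]")
        if self.noise_sd < 0 or self.lacuna_density < 0 or self.fiber_count < 0:
            raise InvalidParameterError("noise_sd, lacuna_density, fiber_count must be >= 0")
        if self.lacuna_density > 0 and self.lacuna_radius_range[1] >= self.lacuna_spacing / 2:
            raise InvalidParameterError("lacuna radius must be < spacing / 2")
        if not 0 < self.surface_band_fraction <= 1:
            raise InvalidParameterError("surface_band_fraction must be in (0, 1]")

    @classmethod
    def cartilage(cls, **overrides) -> "TissueTextureParams":
        return cls(class_name="Cartilage", **overrides)

    @classmethod
    def bone(cls, **overrides) -> "TissueTextureParams":
        defaults = dict(
            class_name="Bone",
            base_intensity=135.0,
            noise_sd=12.0,
            lacuna_density=0.0,
            fiber_count=70,
            fiber_width_px=2.5,
            fiber_gain=55.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def fibrous(cls, **overrides) -> "TissueTextureParams":
        defaults = dict(
            class_name="Fibrous",
            fiber_count=45,
            fiber_width_px=1.6,
            fiber_gain=60.0,
            fiber_orientation_spread=0.3,
            surface_band_fraction=0.25,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _background12(rng, size: int, params: TissueTextureParams) -> np.ndarray:
    """Smooth field plus multiplicative speckle, in 12-bit units."""
    base12 = params.base_intensity * 16.0
    img = np.full((size, size), base12)
    if params.noise_sd > 0:
        field = gaussian_filter(rng.standard_normal((size, size)), 30.0)
        std = field.std()
        if std > 0:
            img = img + field / std * (0.8 * params.noise_sd * 16.0)
        rel = params.noise_sd / max(params.base_intensity, 1.0)
        img = img * (1.0 + rel * rng.standard_normal((size, size)))
    return img


def _carve_lacunae(img12: np.ndarray, rng, params: TissueTextureParams) -> None:
    """Punch dark rotated ellipses at jittered lattice sites, in place."""
    if params.lacuna_density <= 0:
        return
    size = img12.shape[0]
    s = params.lacuna_spacing
    derived_density = (100.0 / s) ** 2
    keep_prob = min(1.0, params.lacuna_density / derived_density)
    r_lo, r_hi = params.lacuna_radius_range
    n_cells = int(np.ceil(size / s))
    for i in range(n_cells):
        for j in range(n_cells):
            if rng.random() > keep_prob:
                continue
            cr = (i + 0.5) * s + rng.uniform(-s / 4, s / 4)
            cc = (j + 0.5) * s + rng.uniform(-s / 4, s / 4)
            r1 = rng.uniform(r_lo, r_hi)
            r2 = rng.uniform(r_lo, r_hi)
            phi = rng.uniform(0, np.pi)
            dark = rng.uniform(0.0, 30.0)  # 12-bit: < 2 gray levels at 8-bit
            if not (0 <= cr < size and 0 <= cc < size):
                continue
            m = int(np.ceil(max(r1, r2))) + 1
            r0, r9 = max(int(cr) - m, 0), min(int(cr) + m + 1, size)
            c0, c9 = max(int(cc) - m, 0), min(int(cc) + m + 1, size)
            rows = np.arange(r0, r9)[:, None] - cr
            cols = np.arange(c0, c9)[None, :] - cc
            u = rows * np.cos(phi) + cols * np.sin(phi)
            v = -rows * np.sin(phi) + cols * np.cos(phi)
            mask = (u / r1) ** 2 + (v / r2) ** 2 <= 1.0
            img12[r0:r9, c0:c9][mask] = dark


def _fiber_canvas(
    rng,
    size: int,
    params: TissueTextureParams,
    row_limit: int | None = None,
) -> np.ndarray:
    """Accumulate bright fiber streaks; returns a 12-bit additive layer.

    Fibers are line segments rasterized onto a canvas then blurred to the
    configured width; ``row_limit`` confines centers and samples to the top
    band (fibrous-cartilage phenotype).
    """
    if params.fiber_count == 0:
        return np.zeros((size, size))
    theta0 = (
        params.fiber_orientation
        if params.fiber_orientation is not None
        else rng.uniform(0, np.pi)
    )
    max_row = row_limit if row_limit is not None else size
    canvas = np.zeros((size, size))
    for _ in range(params.fiber_count):
        theta = theta0 + rng.normal(0.0, params.fiber_orientation_spread)
        cr = rng.uniform(0, max_row)
        cc = rng.uniform(0, size)
        length = rng.uniform(0.4, 1.0) * size
        gain = rng.uniform(0.6, 1.4) * params.fiber_gain
        t = np.linspace(-length / 2, length / 2, max(int(2 * length), 2))
        rows = np.rint(cr - t * np.sin(theta)).astype(int)
        cols = np.rint(cc + t * np.cos(theta)).astype(int)
        ok = (rows >= 0) & (rows < max_row) & (cols >= 0) & (cols < size)
        np.add.at(canvas, (rows[ok], cols[ok]), gain)
    sigma = params.fiber_width_px
    blurred = gaussian_filter(canvas, sigma)
    # line sampling density is 2 points/px; rescale so an isolated fiber
    # peaks near gain*16 in 12-bit units
    return blurred * (np.sqrt(2 * np.pi) * sigma * 16.0 / 2.0)


def _finalize(img12: np.ndarray, params: TissueTextureParams, image_id: str | None) -> GrayImage:
    clipped = np.clip(np.rint(img12), 0, 4095).astype(np.int64)
    return convert_12_to_8bit(clipped, pixel_size_um=params.pixel_size_um, image_id=image_id)


def gen_cartilage_image(
    size: int = 512,
    params: TissueTextureParams | None = None,
    seed=0,
    image_id: str | None = None,
) -> GrayImage:
    """Homogeneous matrix with dark lacunae on a jittered lattice."""
    params = params or TissueTextureParams.cartilage()
    rng = _rng(seed)
    img12 = _background12(rng, size, params)
    _carve_lacunae(img12, rng, params)
    return _finalize(img12, params, image_id)


def gen_bone_image(
    size: int = 512,
    params: TissueTextureParams | None = None,
    seed=0,
    image_id: str | None = None,
) -> GrayImage:
    """Brighter matrix overlaid with anisotropic bright fiber streaks."""
    params = params or TissueTextureParams.bone()
    rng = _rng(seed)
    img12 = _background12(rng, size, params)
    img12 += _fiber_canvas(rng, size, params)
    return _finalize(img12, params, image_id)


def gen_fibrous_image(
    size: int = 512,
    params: TissueTextureParams | None = None,
    seed=0,
    image_id: str | None = None,
) -> GrayImage:
    """Cartilage-like base with an oriented fiber band along the top surface."""
    params = params or TissueTextureParams.fibrous()
    rng = _rng(seed)
    img12 = _background12(rng, size, params)
    _carve_lacunae(img12, rng, params)
    band = int(round(params.surface_band_fraction * size))
    img12 += _fiber_canvas(rng, size, params, row_limit=max(band, 1))
    return _finalize(img12, params, image_id)


_GENERATORS = {
    "Cartilage": (gen_cartilage_image, TissueTextureParams.cartilage),
    "Hyaline": (gen_cartilage_image, TissueTextureParams.cartilage),
    "Bone": (gen_bone_image, TissueTextureParams.bone),
    "Fibrous": (gen_fibrous_image, TissueTextureParams.fibrous),
}


def _jittered(
    params: TissueTextureParams,
    rng,
    jitter: float,
    noise_range_rel: tuple[float, float],
) -> TissueTextureParams:
    """Per-image variation so a dataset is not a set of clones.

    ``noise_range_rel`` is the relative range the per-image speckle
    amplitude is drawn from; widening it (e.g. (0.5, 2.0)) makes within-class
    texture variation dominate and the classification task harder.
    """
    if jitter <= 0 and noise_range_rel == (1.0, 1.0):
        return params
    u = lambda: 1.0 + rng.uniform(-jitter, jitter)
    changes = dict(
        base_intensity=float(np.clip(params.base_intensity * u(), 5, 250)),
        noise_sd=params.noise_sd * rng.uniform(*noise_range_rel),
    )
    if params.fiber_count:
        changes["fiber_count"] = max(int(round(params.fiber_count * u())), 1)
        changes["fiber_gain"] = params.fiber_gain * u()
    if params.class_name == "Fibrous":
        changes["surface_band_fraction"] = float(rng.uniform(0.15, 0.35))
    return replace(params, **changes)


def gen_dataset(
    n_per_class: int,
    classes: tuple[str, ...] = ("Cartilage", "Bone"),
    seed: int = 0,
    size: int = 512,
    jitter: float = 0.15,
    noise_range_rel: tuple[float, float] = (0.85, 1.15),
    out_dir: str | Path | None = None,
    params_by_class: dict[str, TissueTextureParams] | None = None,
) -> tuple[LabeledImageSet, pd.DataFrame]:
    """Generate a labeled image set plus manifest, optionally written to disk.

    Each image gets its own child seed of ``seed``; the manifest records the
    per-image class, seed and jittered intensity parameters so any image can
    be regenerated exactly.
    """
    unknown = set(classes) - set(_GENERATORS)
    if unknown:
        raise InvalidParameterError(f"unknown classes: {sorted(unknown)}")
    children = np.random.SeedSequence(seed).spawn(n_per_class * len(classes))
    images, labels, rows = [], [], []
    idx = 0
    for cls in classes:
        gen, default_params = _GENERATORS[cls]
        base = (params_by_class or {}).get(cls) or default_params()
        for i in range(n_per_class):
            child = children[idx]
            idx += 1
            rng = np.random.default_rng(child)
            p = _jittered(base, rng, jitter, noise_range_rel)
            image_id = f"{cls.lower()}_{i:03d}"
            img = gen(size=size, params=p, seed=rng, image_id=image_id)
            images.append(img)
            labels.append(cls)
            rows.append(
                dict(
                    filename=f"{image_id}.tif",
                    label=cls,
                    seed=int(child.generate_state(1)[0]),
                    base_intensity=round(p.base_intensity, 3),
                    noise_sd=round(p.noise_sd, 3),
                )
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, rows):
            write_image(img, out_dir / row["filename"])
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return LabeledImageSet(images=images, labels=labels), manifest
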