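"""Classical fundus-image preparation: crop, resize, enhance, augment.

The chain mirrors standard screening-pipeline practice: crop tightly to the
retina (drop the uninformative black frame), resize to a square working
resolution (1024x1024 by default), boost local contrast so vessels and
subtle lesions stand out, extract the green channel (where retinal vessels
have the highest contrast), and augment with flips/rotations/photometric
jitter.  All operations are pure: inputs are never modified in place, and
outputs stay uint8 in [0, 255].

Functions accept either a bare ``HxWx3`` (or ``HxW``) uint8 array or a
:class:`FundusImage` wrapper and return plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage import exposure, transform

# ITU-R BT.601 luma weights; override via the `weights` argument
GRAY_WEIGHTS_601 = (0.299, 0.587, 0.114)

DEFAULT_CROP_THRESHOLD = 10
DEFAULT_SIZE = 1024
DEFAULT_CLIP_LIMIT = 0.02
DEFAULT_TILES = (8, 8)


class EmptyRetinaError(ValueError):
    """No pixel exceeded the binarization threshold: nothing to crop to."""


@dataclass
class FundusImage:
    """A fundus photograph plus a provenance note."""

    pixels: np.ndarray
    provenance: str = ""


def _as_array(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, FundusImage) else image
    arr = np.asarray(arr)
    if arr.size == 0 or arr.ndim not in (2, 3):
        raise ValueError(f"expected HxW or HxWx3 image, got shape {arr.shape}")
    return arr


def to_gray(image, weights: Sequence[float] = GRAY_WEIGHTS_601) -> np.ndarray:
    """Luma grayscale of a color image (identity for single-channel input)."""
    arr = _as_array(image)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=True)
    gray = arr[..., :3].astype(float) @ np.asarray(weights, dtype=float)
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def crop_to_retina(image, threshold: int = DEFAULT_CROP_THRESHOLD
                   ) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Crop to the tight bounding rectangle of the bright retina.

    The image is converted to grayscale, binarized at ``threshold``
    (foreground = strictly brighter), and cropped to the foreground's
    bounding box.  Returns ``(crop, (row0, row1, col0, col1))`` with
    half-open bounds.  Idempotent up to one pixel.
    """
    arr = _as_array(image)
    mask = to_gray(arr) > threshold
    if not mask.any():
        raise EmptyRetinaError(
            f"no pixel brighter than threshold {threshold}; cannot locate "
            "the retina")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    return arr[r0:r1, c0:c1].copy(), (r0, r1, c0, c1)


def resize_square(image, size: int = DEFAULT_SIZE) -> np.ndarray:
    """Bilinear resize to ``size`` x ``size`` pixels."""
    arr = _as_array(image)
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    if arr.shape[0] == size and arr.shape[1] == size:
        return arr.copy()
    out = transform.resize(arr, (size, size) + arr.shape[2:], order=1,
                           preserve_range=True, anti_aliasing=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def enhance_contrast(image, clip_limit: float = DEFAULT_CLIP_LIMIT,
                     tile_grid: tuple[int, int] = DEFAULT_TILES) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    Color images are equalized on the luminance channel of YCbCr so hues are
    preserved; ``clip_limit`` is the CLAHE clipping fraction in (0, 1] and
    ``tile_grid`` the number of local tiles per axis.  Constant images are
    returned unchanged (there is no contrast to redistribute).
    """
    from skimage import color

    arr = _as_array(image)
    if arr.min() == arr.max():
        return arr.copy()
    kernel = (max(1, arr.shape[0] // tile_grid[0]),
              max(1, arr.shape[1] // tile_grid[1]))
    if arr.ndim == 2:
        eq = exposure.equalize_adapthist(arr, kernel_size=kernel,
                                         clip_limit=clip_limit)
        return np.clip(np.round(eq * 255), 0, 255).astype(np.uint8)
    ycbcr = color.rgb2ycbcr(arr[..., :3])
    y = (ycbcr[..., 0] - 16.0) / 219.0  # luma lives in [16, 235]
    y_eq = exposure.equalize_adapthist(np.clip(y, 0, 1), kernel_size=kernel,
                                       clip_limit=clip_limit)
    ycbcr[..., 0] = y_eq * 219.0 + 16.0
    rgb = color.ycbcr2rgb(ycbcr)
    return np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)


def green_channel(image) -> np.ndarray:
    """The green plane of a color fundus image, unchanged.

    Vessels show highest contrast against the retinal background in green.
    """
    arr = _as_array(image)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(
            f"green_channel needs a 3-channel image, got shape {arr.shape}")
    return arr[..., 1].copy()


_KNOWN_OPS = ("hflip", "rotate", "contrast", "brightness")


def augment(image, ops_spec: Sequence[dict],
            seed: Optional[int] = None) -> np.ndarray:
    """Apply a deterministic augmentation sequence.

    ``ops_spec`` is a list of dicts: ``{"op": "hflip"}``,
    ``{"op": "rotate", "angle": deg}``, ``{"op": "contrast", "scale": s}``,
    ``{"op": "brightness", "offset": b}``.  Any numeric parameter may be
    replaced by ``"range": [lo, hi]`` to be drawn uniformly under ``seed``.
    Rotation fills exposed corners with black (the fundus background);
    photometric ops clip to [0, 255].
    """
    rng = np.random.default_rng(seed)
    arr = _as_array(image).copy()

    def param(spec: dict, key: str, default: float) -> float:
        if key in spec:
            return float(spec[key])
        if "range" in spec:
            lo, hi = spec["range"]
            return float(rng.uniform(lo, hi))
        return default

    for spec in ops_spec:
        op = spec.get("op")
        if op not in _KNOWN_OPS:
            raise ValueError(f"unknown augmentation op {op!r}; "
                             f"expected one of {_KNOWN_OPS}")
        if op == "hflip":
            arr = arr[:, ::-1].copy()
        elif op == "rotate":
            angle = param(spec, "angle", 0.0)
            if angle % 360 == 0:
                continue
            out = transform.rotate(arr.astype(float), angle, resize=False,
                                   cval=0.0, order=1, preserve_range=True)
            arr = np.clip(np.round(out), 0, 255).astype(np.uint8)
        elif op == "contrast":
            scale = param(spec, "scale", 1.0)
            mean = arr.astype(float).mean()
            out = (arr.astype(float) - mean) * scale + mean
            arr = np.clip(np.round(out), 0, 255).astype(np.uint8)
        else:  # brightness
            offset = param(spec, "offset", 0.0)
            out = arr.astype(float) + offset
            arr = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return arr
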