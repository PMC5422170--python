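"""Single-seed segmentation from RGB images.

The seed is isolated by thresholding two colour bands independently and
combining the results:

1. extract the red band and the hue band from the RGB image;
2. smooth each band and binarize it at an Otsu-optimal threshold;
3. OR the two binary images and fill enclosed holes;
4. AND the resulting mask with the original image.

Images are numpy arrays: RGB images are ``(H, W, 3) uint8``, gray bands
``(H, W) uint8`` and masks ``(H, W) bool``.  Coordinates are 0-based
``(row, col)`` with pixel centres at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

from .errors import DegenerateHistogramError, NoForegroundError, PaddyIdError

__all__ = [
    "SegmentationConfig",
    "extract_red_band",
    "extract_hue_band",
    "smooth",
    "otsu_threshold",
    "binarize",
    "mask_or",
    "fill_holes",
    "largest_component",
    "mask_apply",
    "segment_seed",
]

# 8-connectivity for foreground components, 4-connectivity (the scipy
# default structure) for the background flood used in hole filling.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationConfig:
    """Tunable parameters of :func:`segment_seed`.

    Parameters
    ----------
    smooth_size:
        Side of the square box-mean filter applied to each band before
        thresholding. ``1`` disables smoothing.
    red_polarity, hue_polarity:
        ``"bright"`` (band value above threshold is seed), ``"dark"``
        (at or below threshold is seed) or ``"auto"``: the class
        occupying the smaller share of the image border is taken as the
        seed, since the seed is an interior object.
    keep_largest:
        Retain only the largest 8-connected component of the combined
        mask (single-seed assumption).
    """

    smooth_size: int = 3
    red_polarity: str = "auto"
    hue_polarity: str = "auto"
    keep_largest: bool = True


def _check_color(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise PaddyIdError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    return img


def extract_red_band(img: np.ndarray) -> np.ndarray:
    """Return the red channel of an RGB image as a gray band."""
    return _check_color(img)[:, :, 0].astype(np.uint8)


def extract_hue_band(img: np.ndarray) -> np.ndarray:
    """Return the hue of an RGB image rescaled to 8-bit integers.

    The hue angle in [0, 360) degrees is mapped linearly onto [0, 255].
    Achromatic pixels (R = G = B), for which hue is undefined, map to 0.
    """
    img = _check_color(img)
    hue = rgb2hsv(img)[:, :, 0]  # in [0, 1)
    return np.rint(hue * 255.0).astype(np.uint8)


def smooth(img: np.ndarray, size: int = 3) -> np.ndarray:
    """Box-mean filter a gray band once, replicating edge pixels.

    The output is rounded to the nearest integer intensity.  ``size=1``
    returns the input unchanged.
    """
    img = np.asarray(img)
    if size == 1:
        return img.astype(np.uint8)
    out = ndimage.uniform_filter(img.astype(np.float64), size=size, mode="nearest")
    return np.rint(out).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin histogram of an 8-bit band.

    Returns the threshold t in [0, 255] that maximizes the between-class
    variance of the two classes ``{<= t}`` and ``{> t}``; ties are broken
    by the smallest t.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant (a single intensity value).
    """
    img = np.asarray(img)
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("degenerate histogram: image is constant")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                # pixels at or below t
    m0 = np.cumsum(hist * levels)       # intensity mass at or below t
    total, mass = w0[-1], m0[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mass - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0  # thresholds with an empty class
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def binarize(img: np.ndarray, t: int, polarity: str = "bright") -> np.ndarray:
    """Threshold a gray band into a boolean mask.

    ``polarity="bright"`` marks pixels strictly above t as foreground,
    ``"dark"`` marks pixels at or below t.
    """
    img = np.asarray(img)
    if polarity == "bright":
        return img > t
    if polarity == "dark":
        return img <= t
    raise PaddyIdError(f"unknown polarity {polarity!r}")


def _auto_polarity(mask_bright: np.ndarray) -> np.ndarray:
    """Pick the binarization polarity whose foreground avoids the border."""
    border = np.concatenate(
        [mask_bright[0, :], mask_bright[-1, :], mask_bright[1:-1, 0], mask_bright[1:-1, -1]]
    )
    # seed is an interior object: foreground should be the border-minority class
    if border.mean() > 0.5:
        return ~mask_bright
    return mask_bright


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[:2] != b.shape[:2]:
        raise PaddyIdError(f"dimension mismatch: {a.shape} vs {b.shape}")


def mask_or(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise logical OR of two equally sized masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    _check_same_shape(a, b)
    return a | b


def fill_holes(m: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    return ndimage.binary_fill_holes(np.asarray(m, dtype=bool))


def largest_component(m: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties are broken toward the component discovered first in row-major
    order.  Raises :class:`NoForegroundError` on an empty mask.
    """
    m = np.asarray(m, dtype=bool)
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n == 0:
        raise NoForegroundError("no foreground")
    sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1  # first maximal label = row-major tie-break
    return labels == best


def mask_apply(img: np.ndarray, m: np.ndarray) -> np.ndarray:
    """AND an RGB image with a mask: background pixels become black."""
    img = _check_color(img)
    m = np.asarray(m, dtype=bool)
    _check_same_shape(img, m)
    out = img.copy()
    out[~m] = 0
    return out


def _band_mask(band: np.ndarray, polarity: str, smooth_size: int) -> np.ndarray:
    band = smooth(band, smooth_size)
    t = otsu_threshold(band)
    if polarity == "auto":
        return _auto_polarity(binarize(band, t, "bright"))
    return binarize(band, t, polarity)


def segment_seed(
    img: np.ndarray, cfg: SegmentationConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Segment a single seed from an RGB image.

    Runs the full band pipeline (red and hue band -> smooth -> Otsu ->
    binarize, OR, hole fill, largest component) and masks the original
    image.  Returns ``(mask, masked_image)``.
    """
    cfg = cfg or SegmentationConfig()
    img = _check_color(img)
    red = _band_mask(extract_red_band(img), cfg.red_polarity, cfg.smooth_size)
    hue = _band_mask(extract_hue_band(img), cfg.hue_polarity, cfg.smooth_size)
    mask = fill_holes(mask_or(red, hue))
    if cfg.keep_largest:
        mask = largest_component(mask)
    elif not mask.any():
        raise NoForegroundError("no foreground")
    return mask, mask_apply(img, mask)
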