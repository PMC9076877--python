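"""Channel preprocessing: grayscale normalization, background shading
removal, contrast enhancement, and macular masking.

The fixed order of the pipeline is: grayscale → background-correct →
contrast-stretch → macular mask. Background correction subtracts a Gaussian
blurred copy of the image from itself, which removes slow illumination
gradients (vignetting) while leaving lesion-scale structure; the blur scale
must exceed the largest druse so that lesions survive the subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError

__all__ = [
    "PreprocessConfig",
    "MacularMask",
    "to_gray_normalized",
    "background_correct",
    "contrast_stretch",
    "apply_macular_mask",
    "disc_mask",
    "preprocess_channel",
]

log = logging.getLogger(__name__)

# Rec. 601 luminance weights used to collapse an RGB reference image.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    blur_sigma
        Gaussian scale (pixels) of the background estimate; default 50 px is
        tuned to a ~768-px-wide macular frame and must exceed the largest
        druse radius at whatever resolution is in use.
    saturation_fraction
        Total fraction of pixels saturated by the contrast stretch, split
        evenly between the two tails (default 0.004, i.e. 0.4%).
    mask_radius_fraction
        Radius of the default circular macular mask as a fraction of image
        width (default 0.45).
    """

    blur_sigma: float = 50.0
    saturation_fraction: float = 0.004
    mask_radius_fraction: float = 0.45

    def __post_init__(self) -> None:
        if not self.blur_sigma > 0:
            raise ValidationError("blur_sigma must be > 0")
        if not 0 <= self.saturation_fraction < 0.5:
            raise ValidationError("saturation_fraction must be in [0, 0.5)")
        if not 0 < self.mask_radius_fraction <= 0.5:
            raise ValidationError("mask_radius_fraction must be in (0, 0.5]")


@dataclass(frozen=True)
class MacularMask:
    """Binary analysis region on the reference grid (True = analyzed)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValidationError("macular mask must be 2-D")
        if not m.any():
            raise ValidationError("macular mask is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def indices(self) -> np.ndarray:
        """Flat indices of in-mask pixels, row-major order."""
        return np.flatnonzero(self.mask)


def disc_mask(shape: tuple[int, int], radius_fraction: float = 0.45) -> MacularMask:
    """Default macular mask: a disc centered on the image, radius given as a
    fraction of image width."""
    rows, cols = shape
    radius = radius_fraction * cols
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr - (rows - 1) / 2.0) ** 2 + (cc - (cols - 1) / 2.0) ** 2
    return MacularMask(d2 <= radius**2)


def to_gray_normalized(image: np.ndarray) -> np.ndarray:
    """Convert an 8/16-bit (or float) image to single-channel floats in [0,1].

    Integer images are scaled by their bit-depth maximum; RGB(A) input is
    collapsed with Rec. 601 luminance weights.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValidationError("empty image")
    if img.ndim == 3:
        if img.shape[2] not in (3, 4):
            raise ValidationError(f"unsupported channel count: {img.shape[2]}")
        img = np.tensordot(img[..., :3].astype(float), _LUMA, axes=([2], [0]))
        scale = _bit_depth_max(np.asarray(image))
        return np.clip(img / scale, 0.0, 1.0) if scale != 1.0 else np.clip(img, 0.0, 1.0)
    if img.ndim != 2:
        raise ValidationError(f"expected 2-D or 3-D image, got ndim={img.ndim}")
    out = img.astype(float) / _bit_depth_max(img)
    return np.clip(out, 0.0, 1.0)


def _bit_depth_max(img: np.ndarray) -> float:
    if img.dtype == np.uint8:
        return 255.0
    if img.dtype == np.uint16:
        return 65535.0
    if np.issubdtype(img.dtype, np.integer):
        return float(np.iinfo(img.dtype).max)
    return 1.0


def background_correct(
    image: np.ndarray, blur_sigma: float, valid_mask: np.ndarray | None = None
) -> np.ndarray:
    """Subtract the Gaussian-blurred image from the original.

    The signed residual is re-centered at 0.5 and clipped to [0,1], so local
    contrast is preserved symmetrically around mid-gray. Adding a global
    constant to the input leaves the output unchanged (the blur passes
    constants through).

    When ``valid_mask`` is given, the background estimate is a normalized
    (masked) convolution over valid pixels only — registration fills
    out-of-footprint pixels with 0, and letting those enter a wide blur
    would drag the background estimate down across the field.
    """
    if not blur_sigma > 0:
        raise ValidationError("blur_sigma must be > 0")
    img = np.asarray(image, dtype=float)
    if valid_mask is None:
        background = ndimage.gaussian_filter(img, sigma=blur_sigma, mode="nearest")
    else:
        m = np.asarray(valid_mask, dtype=float)
        if m.shape != img.shape:
            raise ValidationError("valid_mask shape must match image")
        num = ndimage.gaussian_filter(img * m, sigma=blur_sigma, mode="constant")
        den = ndimage.gaussian_filter(m, sigma=blur_sigma, mode="constant")
        background = np.divide(num, den, out=np.full_like(img, img.mean()), where=den > 1e-12)
    return np.clip(img - background + 0.5, 0.0, 1.0)


def contrast_stretch(
    image: np.ndarray,
    saturation_fraction: float = 0.004,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Linear percentile stretch onto [0,1].

    The lower and upper ``saturation_fraction / 2`` quantiles map to 0 and 1;
    values beyond them clip. Quantiles are computed over ``valid_mask``
    pixels when given (the analyzed region), over the whole frame otherwise.
    A constant image is returned unchanged (with a warning) rather than
    dividing by zero.
    """
    if not 0 <= saturation_fraction < 0.5:
        raise ValidationError("saturation_fraction must be in [0, 0.5)")
    img = np.asarray(image, dtype=float)
    sample = img if valid_mask is None else img[np.asarray(valid_mask, bool)]
    lo, hi = np.quantile(sample, [saturation_fraction / 2, 1 - saturation_fraction / 2])
    if hi <= lo:
        log.warning("contrast_stretch: constant image, returning input unchanged")
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def apply_macular_mask(
    image: np.ndarray, mask: MacularMask
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict an image to the macular analysis region.

    Returns ``(masked_image, indices)`` where ``masked_image`` has
    outside-mask pixels zeroed for display and ``indices`` is the flat index
    set of in-mask pixels — downstream statistics operate on the index set,
    never on the zeroed pixels.
    """
    img = np.asarray(image, dtype=float)
    if img.shape != mask.shape:
        raise ValidationError(
            f"image shape {img.shape} does not match mask shape {mask.shape}"
        )
    out = np.where(mask.mask, img, 0.0)
    return out, mask.indices


def preprocess_channel(
    image: np.ndarray, config: PreprocessConfig, mask: MacularMask | None = None
) -> tuple[np.ndarray, MacularMask]:
    """Full preprocessing chain for one channel already on the reference grid.

    Returns the processed raster and the macular mask used (the supplied one,
    or the default centered disc).
    """
    gray = to_gray_normalized(image)
    if mask is None:
        mask = disc_mask(gray.shape, config.mask_radius_fraction)
    corrected = background_correct(gray, config.blur_sigma, valid_mask=mask.mask)
    stretched = contrast_stretch(corrected, config.saturation_fraction, valid_mask=mask.mask)
    masked, _ = apply_macular_mask(stretched, mask)
    return masked, mask
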