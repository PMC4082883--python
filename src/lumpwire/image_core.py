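"""Image loading, normalization, ROI cropping, smoothing and gradients.

Conventions used throughout the package:

* images are 2-D ``float64`` arrays indexed ``(row, col)``, 0-based, row-major;
* ``x`` is the column direction and ``y`` the row direction;
* intensities are min-max normalized to ``[0, 1]`` on load (a constant image
  maps to all zeros — it carries no edge information);
* all filtering uses reflect padding so that no artificial edges are injected
  at the image border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

import imageio.v3 as iio

MIN_SIDE = 16  # smallest side for a meaningful pixel graph


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class IntensityImage:
    """A normalized 2-D grayscale image.

    Parameters
    ----------
    pixels
        2-D float array with values in ``[0, 1]``, shape ``(rows, cols)``,
        at least 16x16.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValidationError(f"image must be 2-D, got ndim={px.ndim}")
        if min(px.shape) < MIN_SIDE:
            raise ValidationError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {px.shape}"
            )
        if not np.isfinite(px).all():
            raise ValidationError("image contains NaN or Inf")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("image intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RoiRect:
    """Rectangular region of interest, half-open in both axes."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValidationError("ROI height and width must be positive")
        if self.top < 0 or self.left < 0:
            raise ValidationError("ROI top/left must be non-negative")


@dataclass(frozen=True)
class GradientField:
    """Partial derivatives I_x (columns), I_y (rows) and gradient magnitude."""

    ix: np.ndarray
    iy: np.ndarray
    magnitude: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.magnitude is None:
            object.__setattr__(
                self, "magnitude", np.hypot(self.ix, self.iy)
            )


def normalize(pixels: np.ndarray) -> np.ndarray:
    """Min-max scale to [0,1]; a constant array maps to all zeros."""
    px = np.asarray(pixels, dtype=np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return np.zeros_like(px)
    return (px - lo) / (hi - lo)


def load_image(path) -> IntensityImage:
    """Read a PNG/TIFF image, convert to luminance if RGB, normalize to [0,1].

    Raises
    ------
    OSError
        If the file cannot be read.
    ValidationError
        If the decoded image is empty or smaller than 16x16.
    """
    arr = iio.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        # ITU-R 601 luma
        arr = arr @ np.array([0.299, 0.587, 0.114])
    return IntensityImage(normalize(arr))


def save_mask_png(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values 0/255."""
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def crop_roi(img: IntensityImage, roi: RoiRect) -> IntensityImage:
    """Extract a sub-image; values are passed through unchanged."""
    rows, cols = img.shape
    if roi.top + roi.height > rows or roi.left + roi.width > cols:
        raise ValidationError(
            f"ROI {roi} exceeds image bounds {img.shape}"
        )
    sub = img.pixels[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width]
    return IntensityImage(sub.copy())


def gaussian_smooth(img: IntensityImage, sigma: float) -> IntensityImage:
    """Gaussian convolution with reflect padding, clipped back to [0,1]."""
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    out = ndimage.gaussian_filter(img.pixels, sigma=sigma, mode="reflect")
    return IntensityImage(np.clip(out, 0.0, 1.0))


def gradients(img: IntensityImage, operator: str = "central") -> GradientField:
    """Partial derivatives of the image.

    ``central`` (default) uses central differences with one-sided stencils at
    the borders (``numpy.gradient``); ``sobel`` uses the Sobel operator with
    reflect padding.
    """
    px = img.pixels
    if operator == "central":
        iy, ix = np.gradient(px)
    elif operator == "sobel":
        ix = ndimage.sobel(px, axis=1, mode="reflect") / 8.0
        iy = ndimage.sobel(px, axis=0, mode="reflect") / 8.0
    else:
        raise ValidationError(f"unknown gradient operator {operator!r}")
    return GradientField(ix=ix, iy=iy)
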