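"""Model-vs-SEM image validation: masking, photometric alignment, relative
difference.

A rendered view of a 3D model and the SEM image it was reconstructed from
share geometry but not photometry: the two sources have different brightness
and contrast.  The validation pipeline therefore (1) extracts the specimen
foreground from the SEM image by edge detection, (2) histogram-matches the
render to the SEM image inside that mask, and (3) computes a per-pixel
relative difference

    reldiff_i = |X_i^M - X_i^S| / X_i^S

where X^M and X^S are the model-render and SEM pixel values.  The statistic
is deliberately asymmetric — it is normalised by the SEM pixel, which is the
measurement; swapping the arguments changes the result.  Pixels where the SEM
value is zero are excluded and counted rather than regularised with an
arbitrary epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import sobel, threshold_otsu
from skimage.morphology import disk

__all__ = [
    "GrayImage",
    "ComparisonResult",
    "MaskError",
    "load_image",
    "save_image",
    "edge_mask",
    "histogram_match",
    "relative_difference",
    "compare_pair",
]

#: Rec. 709 luminance weights used when collapsing an RGB input to grayscale.
LUMA_WEIGHTS = (0.2126, 0.7152, 0.0722)


class MaskError(ValueError):
    """Raised when no usable foreground can be extracted from an image."""


@dataclass
class GrayImage:
    """2D grayscale raster with an explicit bit depth (8 or 16).

    Pixels may be float-valued (e.g. after histogram matching) but always lie
    within ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage expects a 2D array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.pixels.size and (self.pixels.min() < 0
                                 or self.pixels.max() > 2 ** self.bit_depth - 1):
            raise ValueError("pixel values exceed the stated bit depth")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    def as_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)


@dataclass
class ComparisonResult:
    """Outcome of one render-vs-SEM comparison.

    ``reldiff`` is NaN outside the mask and at excluded zero-denominator
    pixels; summary statistics are over the defined pixels only.
    """

    mask: np.ndarray  # bool foreground
    reldiff: np.ndarray  # float64, NaN where undefined
    mean_reldiff: float
    median_reldiff: float
    excluded_zero_pixels: int
    n_defined: int = field(default=0)

    def summary(self) -> dict:
        return {
            "mean_reldiff": self.mean_reldiff,
            "median_reldiff": self.median_reldiff,
            "n_defined": self.n_defined,
            "excluded_zero_pixels": self.excluded_zero_pixels,
            "mask_pixels": int(self.mask.sum()),
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> GrayImage:
    """Load an 8- or 16-bit TIFF or PNG as grayscale.

    RGB(A) inputs are collapsed by Rec. 709 luminance; the alpha channel, if
    any, is ignored.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ np.asarray(LUMA_WEIGHTS)
        arr = np.rint(arr)
    bit_depth = 16 if (arr.dtype.itemsize > 1 or arr.max() > 255) else 8
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    return GrayImage(arr.astype(dtype), bit_depth=bit_depth)


def save_image(arr: np.ndarray, path: str | Path) -> None:
    """Write an array as TIFF (any dtype, e.g. float32 difference maps) or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def edge_mask(image: GrayImage, min_object_fraction: float = 0.01) -> np.ndarray:
    """Foreground mask from edges: Sobel gradient magnitude, Otsu threshold,
    morphological closing, hole filling, then keep the connected components
    covering at least ``min_object_fraction`` of the frame.

    Edge positions depend on intensity ordering, not absolute brightness, so
    the mask is stable under monotone brightness transforms (up to threshold
    effects near the rim).

    Raises
    ------
    MaskError
        If the image has no edges (constant input) or no component passes the
        size filter.
    """
    pixels = image.as_float()
    if np.ptp(pixels) == 0:
        raise MaskError("constant image: no edges to detect")
    grad = sobel(pixels / image.max_value)
    thresh = threshold_otsu(grad)
    edges = grad > thresh
    if not edges.any():
        raise MaskError("no edges above the Otsu threshold")
    closed = ndimage.binary_closing(edges, structure=disk(3))
    filled = ndimage.binary_fill_holes(closed)
    labels, n_labels = ndimage.label(filled)
    if n_labels == 0:
        raise MaskError("no connected foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_labels + 1))
    keep = np.flatnonzero(sizes >= min_object_fraction * pixels.size) + 1
    if keep.size == 0:
        raise MaskError(
            f"no component covers >= {min_object_fraction:.3g} of the frame; "
            "lower min_object_fraction"
        )
    return np.isin(labels, keep)


def histogram_match(source: GrayImage, reference: GrayImage,
                    mask: np.ndarray) -> GrayImage:
    """Photometric alignment by CDF quantile mapping, restricted to the mask.

    Each in-mask source value v is assigned its midpoint (average-rank)
    quantile q = (#{x < v} + ½·#{x = v}) / n and mapped to the reference
    intensity at the same in-mask quantile (linear interpolation between
    reference values).  Out-of-mask pixels pass through unchanged.  The
    midpoint convention makes a constant source map to the reference median,
    and makes the operation exactly idempotent.  Output pixels are
    float-valued within the source's bit-depth range.
    """
    if source.shape != reference.shape or mask.shape != source.shape:
        raise ValueError("source, reference and mask must share dimensions")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")

    src = source.as_float()
    src_in = src[mask]
    ref_in = reference.as_float()[mask]
    n_src, n_ref = src_in.size, ref_in.size

    src_vals, src_counts = np.unique(src_in, return_counts=True)
    cum = np.cumsum(src_counts)
    src_quantiles = (cum - 0.5 * src_counts) / n_src

    ref_vals, ref_counts = np.unique(ref_in, return_counts=True)
    ref_cum = np.cumsum(ref_counts)
    ref_quantiles = (ref_cum - 0.5 * ref_counts) / n_ref

    mapped_vals = np.interp(src_quantiles, ref_quantiles, ref_vals)
    idx = np.searchsorted(src_vals, src_in)
    out = src.copy()
    out[mask] = mapped_vals[idx]
    return GrayImage(np.clip(out, 0, source.max_value), bit_depth=source.bit_depth)


def relative_difference(model_img: GrayImage, sem_img: GrayImage,
                        mask: np.ndarray) -> ComparisonResult:
    """Per-pixel relative difference |X^M − X^S| / X^S inside the mask.

    Pixels with a zero SEM denominator are excluded from the map and the
    statistics and reported in ``excluded_zero_pixels``.
    """
    if model_img.shape != sem_img.shape or mask.shape != model_img.shape:
        raise ValueError("images and mask must share dimensions")
    mask = np.asarray(mask, dtype=bool)
    model = model_img.as_float()
    sem = sem_img.as_float()

    defined = mask & (sem > 0)
    excluded = int(mask.sum() - defined.sum())
    if not defined.any():
        raise ValueError("all in-mask SEM pixels are zero; relative difference undefined")

    reldiff = np.full(model.shape, np.nan)
    reldiff[defined] = np.abs(model[defined] - sem[defined]) / sem[defined]
    values = reldiff[defined]
    return ComparisonResult(
        mask=mask,
        reldiff=reldiff,
        mean_reldiff=float(values.mean()),
        median_reldiff=float(np.median(values)),
        excluded_zero_pixels=excluded,
        n_defined=int(defined.sum()),
    )


def compare_pair(model_img: GrayImage, sem_img: GrayImage,
                 min_object_fraction: float = 0.01) -> ComparisonResult:
    """Full validation pipeline for one pre-aligned render/SEM pair.

    Stages: foreground mask from the SEM image → histogram-match the render
    to the SEM image inside the mask → per-pixel relative difference.  The
    pair must already be registered in scale and viewing angle; geometric
    alignment is the caller's responsibility.  Deterministic: identical
    inputs give bit-identical results.
    """
    mask = edge_mask(sem_img, min_object_fraction=min_object_fraction)
    matched = histogram_match(model_img, sem_img, mask)
    return relative_difference(matched, sem_img, mask)
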