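"""Plant/background segmentation.

Two routes, matching the two imaging systems:

* multispectral stacks — intensity thresholding on one band (fixed value
  or Otsu's method) followed by despeckling (removal of small connected
  components);
* RGB images — thresholding the red:blue intensity ratio (plants absorb
  blue strongly; a gray background does not separate red from blue),
  refined by morphological erosion and dilation.

Thresholds, kernel sizes and iteration counts are data-dependent and all
exposed in :class:`SegmentationParams`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .imaging import BandImage, PixelMask, RGBImage


@dataclasses.dataclass(frozen=True)
class SegmentationParams:
    """Knobs for both segmentation routes.

    ``threshold`` is an intensity for ``fixed_threshold`` (ignored for
    ``otsu``) and a red:blue ratio for ``rb_ratio``. ``plant_above``
    selects the direction of the fixed comparison. Morphology uses a
    square structuring element of odd side ``morph_kernel_px``.
    """

    method: str = "otsu"  # fixed_threshold | otsu | rb_ratio
    threshold: float = 1.2
    plant_above: bool = True
    despeckle_min_px: int = 16
    morph_kernel_px: int = 3
    erode_iter: int = 1
    dilate_iter: int = 1

    def __post_init__(self) -> None:
        if self.method not in ("fixed_threshold", "otsu", "rb_ratio"):
            raise ValueError(f"unknown segmentation method {self.method!r}")
        if self.despeckle_min_px < 0:
            raise ValueError("despeckle_min_px must be >= 0")
        if self.morph_kernel_px < 1 or self.morph_kernel_px % 2 == 0:
            raise ValueError("morph_kernel_px must be odd and >= 1")
        if self.erode_iter < 0 or self.dilate_iter < 0:
            raise ValueError("iteration counts must be nonnegative")


def threshold_mask(band: BandImage, params: SegmentationParams) -> PixelMask:
    """Threshold one band image into a plant mask.

    ``fixed_threshold``: plant = intensity > threshold (or < when
    ``plant_above`` is False). ``otsu``: threshold maximizing between-class
    variance of the 256-bin histogram; a constant image has no separable
    classes and raises ``ValueError``.
    """
    img = band.intensities
    if params.method == "fixed_threshold":
        t = params.threshold
    elif params.method == "otsu":
        if img.min() == img.max():
            raise ValueError(
                "Otsu thresholding undefined on a constant image (no separable classes)"
            )
        t = threshold_otsu(img, nbins=256)
    else:
        raise ValueError(f"threshold_mask does not handle method {params.method!r}")
    flags = img > t if params.plant_above else img < t
    return PixelMask(flags)


def despeckle(mask: PixelMask, min_px: int) -> PixelMask:
    """Drop 8-connected components smaller than ``min_px`` pixels."""
    if min_px < 0:
        raise ValueError("min_px must be >= 0")
    if min_px <= 1 or mask.n_true == 0:
        return PixelMask(mask.flags.copy())
    labels, n = label(mask.flags, connectivity=2, return_num=True)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_px
    keep[0] = False
    return PixelMask(keep[labels])


def _square(side: int) -> np.ndarray:
    return np.ones((side, side), dtype=bool)


def morph_refine(mask: PixelMask, params: SegmentationParams) -> PixelMask:
    """Erode then dilate with the same square kernel.

    With equal iteration counts this is a morphological opening: it removes
    protrusions thinner than the kernel while preserving bulk shape, and is
    idempotent.
    """
    flags = mask.flags
    kernel = _square(params.morph_kernel_px)
    if params.erode_iter > 0:
        flags = ndimage.binary_erosion(
            flags, structure=kernel, iterations=params.erode_iter
        )
    if params.dilate_iter > 0:
        flags = ndimage.binary_dilation(
            flags, structure=kernel, iterations=params.dilate_iter
        )
    return PixelMask(flags)


def rb_ratio_mask(rgb: RGBImage, params: SegmentationParams) -> PixelMask:
    """Segment plants in an RGB image by the red:blue intensity ratio.

    Plants reflect far less blue than red, while a spectrally flat (gray)
    background gives a ratio near 1, so ``red / max(blue, 1) > threshold``
    separates them. The raw mask is then refined with ``morph_refine``.
    """
    if params.method != "rb_ratio":
        raise ValueError("rb_ratio_mask requires method='rb_ratio'")
    if not params.threshold > 0:
        raise ValueError("rb ratio threshold must be positive")
    red = rgb.channel("red").astype(float)
    blue = np.maximum(rgb.channel("blue").astype(float), 1.0)  # guard /0
    raw = PixelMask(red / blue > params.threshold)
    return morph_refine(raw, params)


def segment_stack(
    stack, params: SegmentationParams, band_role: str = "nir"
) -> PixelMask:
    """Default multispectral route: threshold one band, then despeckle.

    NIR is the default thresholding band (largest plant/background
    contrast in vegetation); pick another role where that fails.
    """
    mask = threshold_mask(stack[band_role], params)
    return despeckle(mask, params.despeckle_min_px)


def mask_iou(a: PixelMask, b: PixelMask) -> float:
    """Intersection over union of two masks; 1.0 when both are empty."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a.flags, b.flags).sum()
    if union == 0:
        return 1.0
    inter = np.logical_and(a.flags, b.flags).sum()
    return float(inter / union)
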