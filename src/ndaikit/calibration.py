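"""Gray-card exposure calibration.

A middle-gray reference card reflects 50% at all wavebands, so on an 8-bit
scale it should read 127. Imaging the card under each LED and scaling every
band by ``127 / measured_gray`` makes images taken under different
illuminants directly comparable. The physical system adjusts exposure time;
here the correction is a digital gain, which assumes a linear sensor
response (the single-point gray correction itself already assumes this).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .imaging import BandImage

#: 8-bit intensity a 50%-reflectance card should produce.
GRAY_TARGET = 127.0


@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    """Exposure correction for one band.

    ``exposure_factor = 127 / measured_gray``; ``clipping_risk`` flags
    factors large enough to push bright pixels past 255.
    """

    band_role: str
    measured_gray: float
    exposure_factor: float
    clipping_risk: bool = False


def exposure_correction(measured_gray: float, band_role: str = "") -> CalibrationResult:
    """Compute the gain that maps the measured gray-card mean onto 127.

    Raises ``ValueError`` for a non-positive measurement (saturated-dark
    card). Means above 255 are impossible for 8-bit data and also rejected.
    """
    if not measured_gray > 0:
        raise ValueError(
            f"gray-card mean must be positive, got {measured_gray} (dark or saturated card?)"
        )
    if measured_gray > 255:
        raise ValueError(f"gray-card mean {measured_gray} exceeds the 8-bit range")
    factor = GRAY_TARGET / measured_gray
    # A factor this large can push the image's bright tail past full scale.
    risk = measured_gray < GRAY_TARGET
    return CalibrationResult(
        band_role=band_role,
        measured_gray=float(measured_gray),
        exposure_factor=factor,
        clipping_risk=risk,
    )


def apply_gain(band: BandImage, factor: float) -> tuple[BandImage, int]:
    """Scale intensities by ``factor``, rounding half away from zero.

    Returns the gained image (with ``exposure_scale`` updated) and the
    number of pixels clipped at 255.
    """
    if not factor > 0:
        raise ValueError(f"gain factor must be positive, got {factor}")
    scaled = band.intensities.astype(float) * factor
    rounded = np.floor(scaled + 0.5)  # half away from zero (intensities >= 0)
    n_clipped = int((rounded > 255).sum())
    out = np.clip(rounded, 0, 255).astype(np.uint8)
    gained = BandImage(
        out,
        peak_nm=band.peak_nm,
        fwhm_nm=band.fwhm_nm,
        exposure_scale=band.exposure_scale * factor,
    )
    return gained, n_clipped


def measure_gray_region(
    band: BandImage, region: tuple[int, int, int, int]
) -> float:
    """Mean intensity over a rectangular region ``(x0, y0, width, height)``.

    The region must lie entirely inside the image and contain at least one
    pixel.
    """
    x0, y0, w, h = region
    height, width = band.shape
    if w <= 0 or h <= 0:
        raise ValueError(f"region must contain at least one pixel, got {region}")
    if x0 < 0 or y0 < 0 or x0 + w > width or y0 + h > height:
        raise ValueError(
            f"region {region} exceeds image bounds {width}x{height}"
        )
    return float(band.intensities[y0 : y0 + h, x0 : x0 + w].mean())


def calibrate_band(
    band: BandImage, region: tuple[int, int, int, int], band_role: str = ""
) -> CalibrationResult:
    """Measure the gray card in ``region`` and derive the exposure factor."""
    gray = measure_gray_region(band, region)
    return exposure_correction(gray, band_role=band_role)
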