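"""Domain containers and I/O for band images, color images, masks and index maps.

All rasters are 8-bit. Pixel coordinates are 0-based, row-major, origin at
the top-left corner. Deeper bit depths are rejected rather than rescaled so
that ratio-of-intensity indices never pick up a hidden scale change.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image


class FormatError(ValueError):
    """Raised when a raster does not match the expected layout or bit depth."""


@dataclasses.dataclass(frozen=True)
class BandImage:
    """One 8-bit monochrome image taken under a single narrow-band illuminant.

    Parameters
    ----------
    intensities
        2-D ``uint8`` array of pixel intensities in [0, 255].
    peak_nm
        Peak wavelength of the illuminating LED, nm.
    fwhm_nm
        Full width at half maximum of the LED spectrum, nm.
    exposure_scale
        Cumulative digital gain applied since acquisition (1.0 = raw).
    """

    intensities: np.ndarray
    peak_nm: float
    fwhm_nm: float
    exposure_scale: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2:
            raise FormatError(f"band image must be 2-D, got {arr.ndim} dims")
        if arr.dtype != np.uint8:
            if not np.issubdtype(arr.dtype, np.integer):
                raise FormatError("band intensities must be integers")
            if arr.min() < 0 or arr.max() > 255:
                raise FormatError("band intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "intensities", arr)
        if not self.peak_nm > 0:
            raise ValueError(f"peak_nm must be positive, got {self.peak_nm}")
        if not self.fwhm_nm > 0:
            raise ValueError(f"fwhm_nm must be positive, got {self.fwhm_nm}")
        if not self.exposure_scale > 0:
            raise ValueError("exposure_scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclasses.dataclass(frozen=True)
class SpectralStack:
    """A set of co-registered band images keyed by spectral role.

    Roles are free strings but the index pipeline understands
    ``green``, ``red`` and ``nir``.
    """

    bands: Mapping[str, BandImage]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("stack needs at least one band")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError(f"bands disagree on shape: {sorted(shapes)}")
        object.__setattr__(self, "bands", dict(self.bands))

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def width(self) -> int:
        return self.shape[1]

    @property
    def height(self) -> int:
        return self.shape[0]

    def __getitem__(self, role: str) -> BandImage:
        try:
            return self.bands[role]
        except KeyError:
            raise KeyError(
                f"stack has no {role!r} band (present: {sorted(self.bands)})"
            ) from None


@dataclasses.dataclass(frozen=True)
class RGBImage:
    """8-bit 3-channel color image stored as an (H, W, 3) array."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise FormatError(f"RGB image must be (H, W, 3), got {arr.shape}")
        if arr.dtype != np.uint8:
            if not np.issubdtype(arr.dtype, np.integer):
                raise FormatError("RGB channels must be integers")
            if arr.min() < 0 or arr.max() > 255:
                raise FormatError("RGB channels must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        idx = {"red": 0, "green": 1, "blue": 2}[name]
        return self.pixels[:, :, idx]


@dataclasses.dataclass(frozen=True)
class ReflectanceMap:
    """Per-pixel reflectance in [0, 1] (8-bit intensity / 255 after calibration)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("reflectance map must be 2-D")
        if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
            raise ValueError("reflectance values must lie in [0, 1]")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclasses.dataclass(frozen=True)
class PixelMask:
    """Boolean plant mask over one pixel grid."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.flags, dtype=bool)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "flags", arr)

    @property
    def n_true(self) -> int:
        return int(self.flags.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.flags.shape


@dataclasses.dataclass(frozen=True)
class IndexMap:
    """Per-pixel values of one anthocyanin index restricted to the plant mask.

    ``values`` holds NaN outside ``valid``; ``valid`` marks pixels that are
    inside the plant mask *and* where the index formula was defined.
    ``n_undefined`` counts plant pixels where the formula was undefined
    (e.g. a zero denominator), so for a plant mask ``m``::

        valid.n_true + n_undefined == m.n_true
    """

    name: str
    values: np.ndarray
    valid: PixelMask
    n_undefined: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != self.valid.shape:
            raise ValueError("values and valid mask disagree on shape")
        object.__setattr__(self, "values", arr)
        if self.n_undefined < 0:
            raise ValueError("n_undefined must be nonnegative")

    @property
    def valid_values(self) -> np.ndarray:
        """1-D array of the index values at valid pixels."""
        return self.values[self.valid.flags]


def read_band_image(path: str | Path, peak_nm: float, fwhm_nm: float) -> BandImage:
    """Read an 8-bit single-channel PNG/TIFF and tag it with its band metadata.

    Multi-channel or deeper-than-8-bit files are rejected with
    :class:`FormatError`; a missing or undecodable file raises ``OSError``.
    """
    img = Image.open(path)
    if img.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
        raise FormatError(
            f"{path}: bit depth deeper than 8 not accepted (mode {img.mode})"
        )
    if img.mode != "L":
        n_channels = len(img.getbands())
        if n_channels != 1:
            raise FormatError(
                f"{path}: expected single-channel raster, got {n_channels} channels"
            )
        img = img.convert("L")
    arr = np.asarray(img, dtype=np.uint8)
    return BandImage(arr, peak_nm=peak_nm, fwhm_nm=fwhm_nm)


def write_band_image(band: BandImage, path: str | Path) -> None:
    """Write a band image as 8-bit grayscale PNG/TIFF (bit-exact round trip)."""
    Image.fromarray(band.intensities, mode="L").save(path)


def read_rgb_image(path: str | Path) -> RGBImage:
    """Read an 8-bit 3-channel PNG/TIFF color image."""
    img = Image.open(path)
    if img.mode not in ("RGB", "RGBA"):
        if len(img.getbands()) == 1:
            raise FormatError(f"{path}: expected 3-channel image, got 1 channel")
    arr = np.asarray(img.convert("RGB"), dtype=np.uint8)
    return RGBImage(arr)


def write_rgb_image(rgb: RGBImage, path: str | Path) -> None:
    Image.fromarray(rgb.pixels, mode="RGB").save(path)


def write_mask(mask: PixelMask, path: str | Path) -> None:
    """Serialize a mask as an 8-bit PNG with plant = 255, background = 0."""
    Image.fromarray(np.where(mask.flags, 255, 0).astype(np.uint8), mode="L").save(path)


def read_mask(path: str | Path) -> PixelMask:
    arr = np.asarray(Image.open(path).convert("L"))
    return PixelMask(arr > 127)


def to_reflectance(band: BandImage) -> ReflectanceMap:
    """Convert 8-bit intensities to reflectance by dividing by 255.

    Full scale (255) maps to reflectance 1.0; the conversion is strictly
    monotone in intensity.
    """
    return ReflectanceMap(band.intensities.astype(float) / 255.0)


def write_index_map(
    index_map: IndexMap,
    path: str | Path,
    scale: tuple[float, float] | None = None,
    cmap: str = "viridis",
) -> dict:
    """Render a false-color raster of an index map plus a CSV sidecar.

    Valid pixels are colormapped over ``scale = (lo, hi)`` (data range when
    None), values outside the scale clipped to its endpoints; background and
    undefined pixels are rendered black. The sidecar ``<path>.csv`` lists one
    ``x,y,value`` row per valid pixel, and its header comments record the
    scale and an annotation string ``mean ± sd`` (3 decimals) matching
    :func:`ndaikit.summaries.index_summary`.

    Returns a dict with the scale actually used and the annotation string.
    Raises ``ValueError`` (writing nothing) when no pixel is valid.
    """
    import matplotlib

    if index_map.valid.n_true == 0:
        raise ValueError("index map has no valid pixels; nothing to render")
    vals = index_map.valid_values
    if scale is None:
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:  # degenerate uniform map: widen so colormapping is defined
            lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = float(scale[0]), float(scale[1])
        if not hi > lo:
            raise ValueError("scale must satisfy lo < hi")

    norm = np.clip((index_map.values - lo) / (hi - lo), 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](np.nan_to_num(norm))
    rgb = (rgba[:, :, :3] * 255).round().astype(np.uint8)
    rgb[~index_map.valid.flags] = 0  # background distinct: black

    mean = float(vals.mean())
    sd = float(vals.std())  # population sd, matches index_summary
    annotation = f"{mean:.3f} ± {sd:.3f}"

    path = Path(path)
    Image.fromarray(rgb, mode="RGB").save(path)
    ys, xs = np.nonzero(index_map.valid.flags)
    csv_path = path.with_suffix(path.suffix + ".csv")
    with open(csv_path, "w") as fh:
        fh.write(f"# index: {index_map.name}\n")
        fh.write(f"# scale: {lo!r},{hi!r}\n")
        fh.write(f"# colormap: {cmap}\n")
        fh.write(f"# annotation: {annotation}\n")
        fh.write("x,y,value\n")
        for x, y, v in zip(xs, ys, index_map.values[ys, xs]):
            fh.write(f"{x},{y},{v:.10g}\n")
    return {"scale": (lo, hi), "annotation": annotation, "csv": csv_path}


def read_index_map_csv(path: str | Path) -> list[tuple[int, int, float]]:
    """Read the ``x,y,value`` sidecar written by :func:`write_index_map`."""
    rows: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("x,"):
                continue
            x, y, v = line.strip().split(",")
            rows.append((int(x), int(y), float(v)))
    return rows
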