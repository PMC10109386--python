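"""Per-pixel anthocyanin reflectance indices.

Six indices built from green, red and near-infrared reflectance. All rest
on the same optics: anthocyanins absorb strongly in the green (~500–550 nm)
while red reflectance tracks chlorophyll, so a red-vs-green contrast rises
with anthocyanin concentration and partially cancels chlorophyll variation.

=====  =============================================  ==================
name   formula                                        inputs
=====  =============================================  ==================
NDAI   (red − green) / (red + green)                  intensity or R
NARI   (1/Rg − 1/Rr) / (1/Rg + 1/Rr)                  reflectance
ARI    1/Rg − 1/Rr                                    reflectance
mACI   Rnir / Rg                                      reflectance
mARI   (1/Rg − 1/Rr) · Rnir                           reflectance
RGI    red / green                                    intensity or R
=====  =============================================  ==================

NDAI and RGI are ratios of like quantities and thus scale-invariant, so
they may be computed on raw intensities; the reciprocal-based indices are
defined on reflectance in (0, 1]. NARI is algebraically identical to NDAI
wherever both reflectances are strictly positive.

Pixels where a formula is undefined (zero denominator) are marked undefined
and counted, never given sentinel values.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .imaging import (
    BandImage,
    IndexMap,
    PixelMask,
    ReflectanceMap,
    RGBImage,
    SpectralStack,
    to_reflectance,
)

INDEX_NAMES = ("NDAI", "NARI", "ARI", "mACI", "mARI", "RGI")


@dataclasses.dataclass(frozen=True)
class IndexDefinition:
    """Name, required band roles, and required input scale of one index."""

    name: str
    required_bands: tuple[str, ...]
    input_scale: str  # "any" (scale-invariant) or "reflectance"


DEFINITIONS: dict[str, IndexDefinition] = {
    "NDAI": IndexDefinition("NDAI", ("green", "red"), "any"),
    "NARI": IndexDefinition("NARI", ("green", "red"), "reflectance"),
    "ARI": IndexDefinition("ARI", ("green", "red"), "reflectance"),
    "mACI": IndexDefinition("mACI", ("green", "nir"), "reflectance"),
    "mARI": IndexDefinition("mARI", ("green", "red", "nir"), "reflectance"),
    "RGI": IndexDefinition("RGI", ("green", "red"), "any"),
}


def _as_array(img: ReflectanceMap | BandImage | np.ndarray) -> np.ndarray:
    if isinstance(img, ReflectanceMap):
        return img.values
    if isinstance(img, BandImage):
        return img.intensities.astype(float)
    return np.asarray(img, dtype=float)


def _check_shapes(mask: PixelMask, *arrays: np.ndarray) -> None:
    for arr in arrays:
        if arr.shape != mask.shape:
            raise ValueError(
                f"shape mismatch: image {arr.shape} vs mask {mask.shape}"
            )


def _make_map(
    name: str, values: np.ndarray, defined: np.ndarray, mask: PixelMask
) -> IndexMap:
    valid = mask.flags & defined
    n_undefined = int(mask.n_true - valid.sum())
    out = np.full(values.shape, np.nan)
    out[valid] = values[valid]
    return IndexMap(name=name, values=out, valid=PixelMask(valid), n_undefined=n_undefined)


def ndai(
    green: ReflectanceMap | BandImage | np.ndarray,
    red: ReflectanceMap | BandImage | np.ndarray,
    mask: PixelMask,
) -> IndexMap:
    """Normalized difference anthocyanin index, (red − green)/(red + green).

    Bounded in [−1, 1] for nonnegative inputs and invariant to a common
    scale factor, so intensities and reflectances give identical maps.
    Pixels with red + green = 0 are undefined.
    """
    g, r = _as_array(green), _as_array(red)
    _check_shapes(mask, g, r)
    denom = r + g
    defined = denom != 0
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(defined, (r - g) / np.where(defined, denom, 1.0), np.nan)
    return _make_map("NDAI", vals, defined, mask)


def nari(green_r: ReflectanceMap, red_r: ReflectanceMap, mask: PixelMask) -> IndexMap:
    """Normalized anthocyanin reflectance index on reciprocal reflectances.

    (1/Rg − 1/Rr)/(1/Rg + 1/Rr); algebraically equal to NDAI wherever both
    reflectances are strictly positive. Zero reflectance in either band is
    undefined.
    """
    g, r = _as_array(green_r), _as_array(red_r)
    _check_shapes(mask, g, r)
    defined = (g > 0) & (r > 0)
    gs = np.where(defined, g, 1.0)
    rs = np.where(defined, r, 1.0)
    inv_g, inv_r = 1.0 / gs, 1.0 / rs
    vals = (inv_g - inv_r) / (inv_g + inv_r)
    return _make_map("NARI", vals, defined, mask)


def ari(green_r: ReflectanceMap, red_r: ReflectanceMap, mask: PixelMask) -> IndexMap:
    """Anthocyanin reflectance index, 1/Rg − 1/Rr."""
    g, r = _as_array(green_r), _as_array(red_r)
    _check_shapes(mask, g, r)
    defined = (g > 0) & (r > 0)
    gs = np.where(defined, g, 1.0)
    rs = np.where(defined, r, 1.0)
    vals = 1.0 / gs - 1.0 / rs
    return _make_map("ARI", vals, defined, mask)


def maci(nir_r: ReflectanceMap, green_r: ReflectanceMap, mask: PixelMask) -> IndexMap:
    """Modified anthocyanin content index, Rnir / Rg."""
    n, g = _as_array(nir_r), _as_array(green_r)
    _check_shapes(mask, n, g)
    defined = g > 0
    vals = n / np.where(defined, g, 1.0)
    return _make_map("mACI", vals, defined, mask)


def mari(
    green_r: ReflectanceMap,
    red_r: ReflectanceMap,
    nir_r: ReflectanceMap,
    mask: PixelMask,
) -> IndexMap:
    """Modified anthocyanin reflectance index, (1/Rg − 1/Rr) · Rnir.

    Zero NIR reflectance simply yields 0 (defined); zero green or red
    reflectance is undefined.
    """
    g, r, n = _as_array(green_r), _as_array(red_r), _as_array(nir_r)
    _check_shapes(mask, g, r, n)
    defined = (g > 0) & (r > 0)
    gs = np.where(defined, g, 1.0)
    rs = np.where(defined, r, 1.0)
    vals = (1.0 / gs - 1.0 / rs) * n
    return _make_map("mARI", vals, defined, mask)


def rgi(
    red_r: ReflectanceMap | BandImage | np.ndarray,
    green_r: ReflectanceMap | BandImage | np.ndarray,
    mask: PixelMask,
) -> IndexMap:
    """Red-to-green ratio index, red / green (scale-invariant)."""
    r, g = _as_array(red_r), _as_array(green_r)
    _check_shapes(mask, r, g)
    defined = g != 0
    vals = r / np.where(defined, g, 1.0)
    return _make_map("RGI", vals, defined, mask)


def compute_index(
    source: SpectralStack | RGBImage,
    definition: IndexDefinition | str,
    mask: PixelMask,
) -> IndexMap:
    """Dispatch one index computation against a spectral stack or RGB image.

    For reflectance-scale indices, band intensities are divided by 255
    first. RGB sources supply only the red and green color channels
    (standing in for the red and green band images), so NIR-based indices
    require a spectral stack. Ratio indices on a stack require a common
    ``exposure_scale`` across the bands involved: with per-band gains the
    gains no longer cancel.
    """
    if isinstance(definition, str):
        try:
            definition = DEFINITIONS[definition]
        except KeyError:
            raise KeyError(
                f"unknown index {definition!r}; known: {sorted(DEFINITIONS)}"
            ) from None

    if isinstance(source, RGBImage):
        available = {"red": source.channel("red"), "green": source.channel("green")}
        for role in definition.required_bands:
            if role not in available:
                raise KeyError(
                    f"{definition.name} needs band {role!r}, which an RGB image cannot supply"
                )
        planes = {role: available[role].astype(float) for role in definition.required_bands}
        if definition.input_scale == "reflectance":
            planes = {k: v / 255.0 for k, v in planes.items()}
    else:
        scales = set()
        planes = {}
        for role in definition.required_bands:
            if role not in source.bands:
                raise KeyError(
                    f"{definition.name} needs band {role!r}, missing from stack "
                    f"(present: {sorted(source.bands)})"
                )
            band = source[role]
            scales.add(band.exposure_scale)
            planes[role] = (
                to_reflectance(band).values
                if definition.input_scale == "reflectance"
                else band.intensities.astype(float)
            )
        if len(scales) > 1:
            raise ValueError(
                f"bands {definition.required_bands} carry different exposure scales "
                f"{sorted(scales)}; calibrate to a common scale before computing indices"
            )

    name = definition.name
    if name == "NDAI":
        return ndai(planes["green"], planes["red"], mask)
    if name == "NARI":
        return nari(planes["green"], planes["red"], mask)
    if name == "ARI":
        return ari(planes["green"], planes["red"], mask)
    if name == "mACI":
        return maci(planes["nir"], planes["green"], mask)
    if name == "mARI":
        return mari(planes["green"], planes["red"], planes["nir"], mask)
    if name == "RGI":
        return rgi(planes["red"], planes["green"], mask)
    raise KeyError(f"unknown index {name!r}")
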