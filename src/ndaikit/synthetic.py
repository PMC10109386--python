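"""Synthetic leaf-disc and rosette scenes with known ground truth.

Every pipeline stage (calibration, segmentation, index computation,
summaries, regression evaluation) can be exercised end-to-end on scenes
generated here, with per-object pigment levels known exactly.

Forward model
-------------
Reflectance responds to pigments through a Beer–Lambert-style exponential:

    R_green = Rg0 · exp(−anth_green·c − chl_green·chl)
    R_red   = Rr0 · exp(−chl_red·chl)
    R_nir   = Rn0                      (structural, pigment-independent)
    R_blue  = Rb0 · exp(−chl_blue·chl) (chlorophyll/carotenoid absorption)

with anthocyanin concentration ``c`` in µg g⁻¹ FW and chlorophyll ``chl``
in arbitrary units. Green reflectance falls with anthocyanin (strong green
absorption) and with chlorophyll; red reflectance falls with chlorophyll
only; NIR is decoupled from pigments entirely. The default coefficients
put object-mean NDAI roughly in [−0.10, 0.20] across the default
concentration span of 108–1673 µg g⁻¹ FW, the range red lettuce shows.

Pixel noise is Gaussian in reflectance units (default sd 0.02, a typical
shot/readout level for 8-bit imagery), clipped to [0, 1] and quantized to
8-bit. The background is spectrally flat.

RGB rendering integrates a per-pixel coarse reflectance spectrum —
piecewise-linear through the blue/green/red/NIR anchors, held flat beyond
them — against broad Gaussian channel sensitivities weighted by a
warm-white illuminant, emulating a color camera whose channels overlap
across the whole visible range.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import BandImage, PixelMask, RGBImage, SpectralStack
from .indices import DEFINITIONS, compute_index
from .segmentation import SegmentationParams, segment_stack
from .summaries import index_summary

#: TopView-style band metadata: role -> (peak nm, FWHM nm)
BAND_METADATA = {"green": (516.0, 40.0), "red": (664.0, 25.0), "nir": (861.0, 28.0)}

#: Anchor wavelengths (nm) of the coarse per-pixel reflectance spectrum.
ANCHOR_NM = np.array([450.0, 516.0, 664.0, 861.0])


@dataclasses.dataclass(frozen=True)
class ForwardModel:
    """Pigment-to-reflectance forward model plus imaging noise."""

    base_green: float = 0.30
    base_red: float = 0.25
    base_nir: float = 0.50
    base_blue: float = 0.06
    anth_green: float = 3.8e-4  # per µg g⁻¹ FW
    chl_green: float = 0.10
    chl_red: float = 0.15
    chl_blue: float = 0.05
    noise_sd: float = 0.02  # reflectance units
    background_reflectance: float = 0.08

    def __post_init__(self) -> None:
        for name in ("base_green", "base_red", "base_nir", "base_blue"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("anth_green", "chl_green", "chl_red", "chl_blue", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.background_reflectance <= 1:
            raise ValueError("background_reflectance must lie in [0, 1]")

    def reflectances(self, c: float, chl: float) -> dict[str, float]:
        """Noiseless band reflectances of a leaf with pigments (c, chl)."""
        return {
            "blue": self.base_blue * np.exp(-self.chl_blue * chl),
            "green": self.base_green * np.exp(-self.anth_green * c - self.chl_green * chl),
            "red": self.base_red * np.exp(-self.chl_red * chl),
            "nir": self.base_nir,
        }


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Geometry and pigment sampling of one synthetic scene.

    Per-object pigments may be given explicitly (``anthocyanin``,
    ``chlorophyll`` sequences of length ``n_objects``) or sampled
    uniformly from ``anth_range`` / ``chl_range``.
    """

    layout: str = "discs"  # discs | rosette
    n_objects: int = 2
    width: int = 96
    height: int = 96
    disc_radius_px: int | None = None
    anthocyanin: Sequence[float] | None = None
    chlorophyll: Sequence[float] | None = None
    anth_range: tuple[float, float] = (108.0, 1673.0)  # µg g⁻¹ FW span observed in red lettuce
    chl_range: tuple[float, float] = (0.8, 1.2)  # modest within-cultivar spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("discs", "rosette"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if self.width < 8 or self.height < 8:
            raise ValueError("scene must be at least 8x8 pixels")
        for vals, name in ((self.anthocyanin, "anthocyanin"), (self.chlorophyll, "chlorophyll")):
            if vals is not None and len(vals) != self.n_objects:
                raise ValueError(f"{name} must list one value per object")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score a pipeline run on a synthetic scene."""

    mask: PixelMask
    labels: np.ndarray  # 0 = background, 1..n = object id
    anthocyanin: np.ndarray  # per object, µg g⁻¹ FW
    chlorophyll: np.ndarray  # per object, arbitrary units
    noiseless_reflectance: dict[str, np.ndarray]  # role -> 2-D map (blue/green/red/nir)
    model: ForwardModel
    seed: int

    def object_mask(self, obj: int) -> PixelMask:
        return PixelMask(self.labels == obj)


@dataclasses.dataclass(frozen=True)
class CameraModel:
    """Gaussian channel sensitivities under a broadband illuminant.

    Peaks/widths default to a consumer camera under warm-white LEDs:
    blue 450 nm; green peak 521 nm with >50% sensitivity over 477–595 nm
    (FWHM 118 nm); red peak 596 nm with >50% over 580–700 nm (FWHM
    120 nm). ``illuminant = None`` means spectrally flat.
    """

    blue_peak_nm: float = 450.0
    blue_fwhm_nm: float = 100.0
    green_peak_nm: float = 521.0
    green_fwhm_nm: float = 118.0
    red_peak_nm: float = 596.0
    red_fwhm_nm: float = 120.0
    grid_nm: np.ndarray = dataclasses.field(
        default_factory=lambda: np.arange(400.0, 701.0, 2.0)
    )
    illuminant: str | None = "warm_white"  # "warm_white" | None (flat)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid_nm, dtype=float)
        if grid.size == 0:
            raise ValueError("wavelength grid is empty")
        if grid.min() > 400 or grid.max() < 700:
            raise ValueError("wavelength grid must cover 400-700 nm")
        object.__setattr__(self, "grid_nm", grid)

    def _gaussian(self, peak: float, fwhm: float) -> np.ndarray:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        s = np.exp(-0.5 * ((self.grid_nm - peak) / sigma) ** 2)
        return s / s.max()  # unit peak

    def illuminant_spectrum(self) -> np.ndarray:
        if self.illuminant is None:
            return np.ones_like(self.grid_nm)
        # warm-white LED: narrow blue pump + broad phosphor hump near 600 nm
        pump = np.exp(-0.5 * ((self.grid_nm - 450.0) / 10.0) ** 2)
        phosphor = np.exp(-0.5 * ((self.grid_nm - 600.0) / 55.0) ** 2)
        spec = 0.25 * pump + phosphor
        return spec / spec.max()

    def effective_responses(self) -> dict[str, np.ndarray]:
        """Per-channel sensitivity × illuminant, renormalized to unit peak."""
        illum = self.illuminant_spectrum()
        out = {}
        for name, peak, fwhm in (
            ("blue", self.blue_peak_nm, self.blue_fwhm_nm),
            ("green", self.green_peak_nm, self.green_fwhm_nm),
            ("red", self.red_peak_nm, self.red_fwhm_nm),
        ):
            eff = self._gaussian(peak, fwhm) * illum
            out[name] = eff / eff.max()
        return out


# ---------------------------------------------------------------------------
# geometry


def _paint_labels(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros((h, w), dtype=np.int32)
    if spec.layout == "discs":
        cols = int(np.ceil(np.sqrt(spec.n_objects)))
        rows = int(np.ceil(spec.n_objects / cols))
        cell_w, cell_h = w / cols, h / rows
        radius = spec.disc_radius_px
        if radius is None:
            radius = max(2, int(0.35 * min(cell_w, cell_h)))
        if 2 * radius + 2 > min(cell_w, cell_h):
            raise ValueError(
                f"disc radius {radius} px does not fit the {cols}x{rows} grid of a "
                f"{w}x{h} image; discs would overlap the border or each other"
            )
        for k in range(spec.n_objects):
            r, c = divmod(k, cols)
            cy, cx = (r + 0.5) * cell_h, (c + 0.5) * cell_w
            labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = k + 1
    else:  # rosette: elliptical leaves radiating from the image center
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        leaf_len = 0.42 * min(h, w)
        leaf_half_w = max(2.0, 0.16 * min(h, w))
        angles = rng.uniform(0, 2 * np.pi) + np.arange(spec.n_objects) * (
            2 * np.pi / spec.n_objects
        )
        for k, theta in enumerate(angles):
            # leaf center halfway along its axis
            ly = cy + 0.5 * leaf_len * np.sin(theta)
            lx = cx + 0.5 * leaf_len * np.cos(theta)
            dy, dx = yy - ly, xx - lx
            along = dx * np.cos(theta) + dy * np.sin(theta)
            across = -dx * np.sin(theta) + dy * np.cos(theta)
            inside = (along / (leaf_len / 2.0)) ** 2 + (across / leaf_half_w) ** 2 <= 1.0
            labels[inside] = k + 1  # later leaves overlap earlier ones
    return labels


def _pigments(spec: SceneSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if spec.anthocyanin is not None:
        c = np.asarray(spec.anthocyanin, dtype=float)
    else:
        c = rng.uniform(*spec.anth_range, size=spec.n_objects)
    if spec.chlorophyll is not None:
        chl = np.asarray(spec.chlorophyll, dtype=float)
    else:
        chl = rng.uniform(*spec.chl_range, size=spec.n_objects)
    return c, chl


def _noiseless_maps(
    spec: SceneSpec, model: ForwardModel, labels: np.ndarray,
    c: np.ndarray, chl: np.ndarray,
) -> dict[str, np.ndarray]:
    maps = {}
    for role in ("blue", "green", "red", "nir"):
        lut = np.empty(spec.n_objects + 1)
        lut[0] = model.background_reflectance
        for k in range(spec.n_objects):
            lut[k + 1] = model.reflectances(c[k], chl[k])[role]
        maps[role] = lut[labels]
    return maps


def _quantize(reflectance: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(reflectance * 255.0 + 0.5), 0, 255).astype(np.uint8)


def _build_truth(
    spec: SceneSpec, model: ForwardModel, rng: np.random.Generator
) -> GroundTruth:
    labels = _paint_labels(spec, rng)
    c, chl = _pigments(spec, rng)
    maps = _noiseless_maps(spec, model, labels, c, chl)
    return GroundTruth(
        mask=PixelMask(labels > 0),
        labels=labels,
        anthocyanin=c,
        chlorophyll=chl,
        noiseless_reflectance=maps,
        model=model,
        seed=spec.seed,
    )


def _noisy(map_: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return map_.copy()
    return np.clip(map_ + rng.normal(0.0, sd, size=map_.shape), 0.0, 1.0)


# ---------------------------------------------------------------------------
# renderers


def render_multispectral(
    spec: SceneSpec, model: ForwardModel | None = None
) -> tuple[SpectralStack, GroundTruth]:
    """Render green/red/NIR band images of a synthetic scene.

    Deterministic for a fixed (spec, model): the spec's seed drives layout,
    pigment sampling and pixel noise.
    """
    model = model or ForwardModel()
    rng = np.random.default_rng(spec.seed)
    truth = _build_truth(spec, model, rng)
    bands = {}
    for role in ("green", "red", "nir"):
        noisy = _noisy(truth.noiseless_reflectance[role], model.noise_sd, rng)
        peak, fwhm = BAND_METADATA[role]
        bands[role] = BandImage(_quantize(noisy), peak_nm=peak, fwhm_nm=fwhm)
    return SpectralStack(bands), truth


def _anchor_weights(camera: CameraModel) -> dict[str, np.ndarray]:
    """Per-channel weights of the four anchor reflectances.

    The per-pixel spectrum is piecewise-linear through the anchors (held
    flat outside), so integrating it against a channel response is a fixed
    linear combination of the anchor maps; the weights of each channel sum
    to 1, hence a spectrally flat pixel maps to its own reflectance.
    """
    grid = camera.grid_nm
    n_anchor = ANCHOR_NM.size
    interp_w = np.zeros((grid.size, n_anchor))
    for j, lam in enumerate(grid):
        if lam <= ANCHOR_NM[0]:
            interp_w[j, 0] = 1.0
        elif lam >= ANCHOR_NM[-1]:
            interp_w[j, -1] = 1.0
        else:
            k = int(np.searchsorted(ANCHOR_NM, lam) - 1)
            t = (lam - ANCHOR_NM[k]) / (ANCHOR_NM[k + 1] - ANCHOR_NM[k])
            interp_w[j, k] = 1.0 - t
            interp_w[j, k + 1] = t
    out = {}
    for name, resp in camera.effective_responses().items():
        w = resp @ interp_w / resp.sum()
        out[name] = w
    return out


def render_rgb(
    spec: SceneSpec,
    model: ForwardModel | None = None,
    camera: CameraModel | None = None,
) -> tuple[RGBImage, GroundTruth]:
    """Render a color image of the same scene a spectral stack would show.

    Channel value = Σλ response·reflectance / Σλ response, quantized to
    8-bit. Broad, overlapping channel responses mix the anchors, so
    RGB-derived indices track—but do not equal—their multispectral
    counterparts.
    """
    model = model or ForwardModel()
    camera = camera or CameraModel()
    rng = np.random.default_rng(spec.seed)
    truth = _build_truth(spec, model, rng)
    weights = _anchor_weights(camera)
    noisy_anchors = [
        _noisy(truth.noiseless_reflectance[role], model.noise_sd, rng)
        for role in ("blue", "green", "red", "nir")
    ]
    channels = {}
    for name in ("red", "green", "blue"):
        w = weights[name]
        chan = sum(wk * mk for wk, mk in zip(w, noisy_anchors))
        channels[name] = _quantize(np.clip(chan, 0.0, 1.0))
    pixels = np.stack([channels["red"], channels["green"], channels["blue"]], axis=-1)
    return RGBImage(pixels), truth


# ---------------------------------------------------------------------------
# evaluation sets


def make_evaluation_set(
    n_samples: int = 50,
    spec_template: SceneSpec | None = None,
    model: ForwardModel | None = None,
    seed: int = 0,
    indices: Sequence[str] = ("NDAI", "ARI", "mACI", "mARI", "RGI"),
    segmentation: SegmentationParams | None = None,
    include_noise_dummy: bool = False,
    csv_path=None,
) -> pd.DataFrame:
    """Render single-disc scenes and tabulate object-mean indices.

    Emulates a leaf-disc calibration study: each sample is one disc with
    its own anthocyanin/chlorophyll level; the full pipeline (render →
    segment → index → summarize) produces one row of
    ``sample_id, concentration_ug_g, <index columns>`` per sample.
    ``include_noise_dummy`` appends a pure-noise pseudo-index column as a
    negative control for evaluation ranking.
    """
    if n_samples < 5:
        raise ValueError("an evaluation set needs at least 5 samples")
    for name in indices:
        if name not in DEFINITIONS:
            raise KeyError(f"unknown index {name!r}")
    model = model or ForwardModel()
    template = spec_template or SceneSpec(layout="discs", n_objects=1)
    seg = segmentation or SegmentationParams(method="otsu")
    master = np.random.default_rng(seed)
    scene_seeds = master.integers(0, 2**31 - 1, size=n_samples)
    rows = []
    for i in range(n_samples):
        spec = dataclasses.replace(
            template, n_objects=1, seed=int(scene_seeds[i])
        )
        stack, truth = render_multispectral(spec, model)
        mask = segment_stack(stack, seg)
        if mask.n_true == 0:  # fall back to truth only if segmentation found nothing
            raise RuntimeError(f"segmentation found no plant pixels in sample {i}")
        row = {"sample_id": f"S{i:03d}", "concentration_ug_g": truth.anthocyanin[0]}
        for name in indices:
            imap = compute_index(stack, name, mask)
            row[name] = index_summary(imap).mean
        rows.append(row)
    table = pd.DataFrame(rows)
    if include_noise_dummy:
        table["noise_dummy"] = master.normal(0.0, 1.0, size=n_samples)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return table
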