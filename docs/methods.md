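# Methods

## The measurement model

All indices treat a calibrated 8-bit pixel intensity as a measure of
reflectance: after gray-card exposure correction, reflectance is
approximated as intensity / 255, so a 50%-reflectance surface reads 127.
Calibration is a single global digital gain per band,
`factor = 127 / measured_gray`, applied with half-away-from-zero rounding
and clipping at 255 (clipped pixels are counted and reported). This
assumes a linear sensor response — the same assumption a single-point
gray correction makes physically — and deliberately targets the integer
127 rather than 127.5, accepting a ≤ 0.4% bias in exchange for the
conventional 8-bit mid-gray definition. No flat-field or gamma
correction is attempted.

Ratio indices (NDAI, RGI) are invariant to a common gain, so they may be
computed on intensities directly; the reciprocal-based indices (NARI,
ARI, mARI, mACI) are defined on reflectance in (0, 1] and inputs are
converted first. When bands of a stack carry *different* accumulated
gains, ratio indices no longer cancel them, so `compute_index` refuses
mixed `exposure_scale` stacks rather than silently mixing scales.

Undefined pixels (zero denominators: green + red = 0 for NDAI, a zero
reflectance for the reciprocal indices, zero green for mACI/RGI) are
excluded from the map and counted in `n_undefined`, never filled with
sentinels. The bookkeeping identity
`valid + undefined + background = total pixels` is enforced by tests.

## Band substitutions

The index formulas from the remote-sensing literature are defined at
550/530 nm (green), 700 nm (red edge) and 940/760+ nm (NIR). The
multispectral system modeled here illuminates at 516 nm (FWHM 40),
664 nm (FWHM 25) and 861 nm (FWHM 28); these are the closest available
wavebands and are used as stand-ins throughout, with the substitution
recorded in each band's metadata rather than hidden. For RGB images the
red and green color channels substitute for the red and green band
images; blue is used only for segmentation.

## Segmentation

Multispectral: threshold one band — default NIR, where the
plant/background contrast of vegetation is largest — either at a fixed
intensity or by Otsu's method (maximizing between-class variance over
the 256-bin histogram; a constant image is rejected as having no
separable classes), then remove 8-connected components smaller than
`despeckle_min_px` (default 16 px).

RGB: plants absorb blue strongly, so `red / max(blue, 1) > threshold`
(default 1.2) separates them from a spectrally flat background; the raw
mask is refined by erosion then dilation with a 3×3 square kernel, one
iteration each (a morphological opening, hence idempotent). All
parameters are exposed because real scenes differ; the defaults are
starting points, not claims.

## Regression evaluation

Index evaluation regresses object-mean index on measured anthocyanin
concentration (concentration is the predictor, matching how calibration
curves are plotted; inversion is a separate explicit operation restricted
to the fitted, monotone range). Ordinary least squares via statsmodels;
reported metrics:

* R² = 1 − RSS/TSS
* RMSE = √(RSS/n) — n denominator, index units
* AIC = n·ln(RSS/n) + 2k with k = number of coefficients + 1, the
  least-squares form with the error variance counted as a parameter
* p-value of the overall F-test (not the highest-order coefficient test)

Model selection fits linear and quadratic and keeps the lower AIC, ties
(|ΔAIC| < 1e-9) going to the linear model; with n < 4 the quadratic is
infeasible and the linear fit is returned flagged. Per-object standard
deviations are population (n-denominator) statistics. Histograms default
to 50 bins over [−1, 1] for the bounded NDAI/NARI and the data range
otherwise.

## Synthetic scene generator

The generator exists so every pipeline stage has ground truth. Pigments
map to band reflectance through a Beer–Lambert-style exponential:

    R_green = 0.30 · exp(−3.8·10⁻⁴·c − 0.10·chl)
    R_red   = 0.25 · exp(−0.15·chl)
    R_nir   = 0.50
    R_blue  = 0.06 · exp(−0.05·chl)

with anthocyanin `c` in µg g⁻¹ FW and chlorophyll `chl` in arbitrary
units (1 ≈ a typical leaf). Only the directionality of these responses
is established physiology — green reflectance falls with anthocyanin and
chlorophyll, red falls with chlorophyll only, NIR reflects leaf structure
rather than pigments — so the exponential form and coefficients are this
package's own design. The coefficients were chosen analytically so that
object-mean NDAI spans roughly −0.10 to 0.20 across the default
concentration range of 108–1673 µg g⁻¹ FW, the span reported for red
lettuce at disc and canopy scale. The blue band is not part of the index
algebra; it exists because RGB rendering and red:blue segmentation need
a blue anchor, and plants absorb blue strongly regardless of anthocyanin.

Defaults that define the simulated study conditions:

| parameter | default | meaning |
|---|---|---|
| anthocyanin range | 108–1673 µg g⁻¹ FW | observed span in red lettuce |
| chlorophyll range | 0.8–1.2 a.u. | modest within-cultivar spread; one species, one growth protocol — anthocyanin, not chlorophyll, is the treatment axis |
| noise sd | 0.02 reflectance units | typical shot/readout noise for 8-bit imagery |
| background reflectance | 0.08, spectrally flat | dark matte chamber floor |
| scene | 96×96 px, discs on a grid | discs sized to fit without touching the border (oversized discs are an error) |

Noise is Gaussian per pixel in reflectance, clipped to [0, 1], then
quantized to 8-bit (×255, half-away-from-zero); noiseless maps therefore
round-trip through quantization within 1/510. All randomness flows from
a single seed; renders are bit-reproducible.

RGB rendering builds, per pixel, a coarse reflectance spectrum —
piecewise-linear through the blue/516/664/861 nm anchors, held flat
outside — and integrates it against channel responses on a 400–700 nm
grid. Channel responses are unit-peak Gaussians (blue 450 nm FWHM 100;
green 521 nm FWHM 118, matching a >50% span of 477–595 nm; red 596 nm
FWHM 120, matching 580–700 nm) multiplied by a warm-white LED illuminant
(narrow 450 nm pump plus a broad phosphor hump near 600 nm) and
renormalized. Because integration against a piecewise-linear spectrum is
linear in the anchors, each channel is computed exactly as a fixed
weighted sum of the four anchor maps; the weights sum to 1, so a
spectrally flat pixel reproduces its own reflectance (the gray-world
property). Shrinking the green/red channel widths onto 516/664 nm makes
RGB-NDAI converge to multispectral NDAI, which is tested.

## What the generator does and does not emulate

It emulates: monotone pigment–reflectance coupling, chlorophyll as a
confounder that red-band indices cancel better than NIR-band ones,
8-bit quantization, additive sensor noise, broad overlapping RGB channel
responses under non-flat illumination, and a flat background. It does
not emulate: specular highlights and shadows, out-of-focus blur,
within-leaf pigment gradients, canopy self-occlusion, or full
radiative-transfer leaf optics (PROSPECT-class models). Passing tests
therefore demonstrate the pipeline's correctness and its behavior under
the stated noise model — not field performance on real canopies.

## Problem sizes

The test suite and acceptance checks use 96×96-pixel scenes, 20-scene
segmentation batches, 50-disc evaluation sets and 25-scene cross-system
comparisons; these sizes give stable statistics (hundreds of plant
pixels per object, ranks over 25–50 objects) while keeping the whole
suite to a few seconds.

## Known limitations

* Calibration is global; vignetting or per-pixel gain variation is out
  of scope.
* Otsu on a nearly unimodal image will produce an arbitrary split; the
  caller should prefer a fixed threshold when the background dominates.
* The red:blue ratio rule assumes a spectrally flat background; colored
  backgrounds need a different rule, and the morphology defaults will
  need retuning per imaging setup.
* `predict_concentration` refuses non-monotone quadratics and
  extrapolation rather than guessing.
* Index values depend on the illumination spectrum; comparisons are only
  valid within one lighting condition, which the synthetic camera model
  makes explicit rather than solving.
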