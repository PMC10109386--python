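# ndaikit

Image-based phenotyping of anthocyanin content in plants. Anthocyanins —
the red/purple pigments of red lettuce, grape skin and autumn leaves —
absorb strongly in the green part of the spectrum (~500–550 nm), while
reflectance in the red (~600–700 nm) tracks chlorophyll instead. A
red-vs-green reflectance contrast therefore rises with anthocyanin
concentration and partially cancels chlorophyll interference, which makes
rapid, non-destructive, camera-only anthocyanin estimation possible.

`ndaikit` is for plant scientists, breeders and controlled-environment
growers who want that estimate from either a multispectral imaging system
(narrow-band LED illumination, monochrome camera) or an ordinary RGB
camera. It provides:

* **Indices** — per-pixel computation of the normalized difference
  anthocyanin index

  NDAI = (I_red − I_green) / (I_red + I_green)

  and five companion indices from the literature:
  NARI = (R_g⁻¹ − R_r⁻¹)/(R_g⁻¹ + R_r⁻¹) (algebraically identical to
  NDAI), ARI = R_g⁻¹ − R_r⁻¹, mACI = R_nir/R_g,
  mARI = (R_g⁻¹ − R_r⁻¹)·R_nir, and RGI = R_r/R_g, with explicit
  accounting of pixels where a formula is undefined. NDAI is bounded in
  [−1, 1]; the others are not.
* **Calibration** — single-point gray-card exposure correction
  (factor = 127 / measured card intensity) that puts bands imaged under
  different LEDs on one reflectance scale.
* **Segmentation** — plant/background separation by intensity
  thresholding (fixed or Otsu) plus despeckling for multispectral stacks,
  and red:blue ratio thresholding plus morphological opening for RGB
  images.
* **Summaries & evaluation** — per-object mean/sd/CV/histograms, and OLS
  regression of index means on measured anthocyanin concentration
  (µg g⁻¹ FW) with R², RMSE, AIC (least-squares form n·ln(RSS/n) + 2k)
  and linear-vs-quadratic model selection.
* **Synthetic scenes** — a generator of leaf-disc and rosette images with
  known per-object pigment levels, so the entire pipeline can be tested
  end to end without any camera.

## Worked example

Render a two-disc synthetic scene (anthocyanin 300 and 1400 µg g⁻¹ FW),
segment it, and compute all indices (`examples/02_leaf_disc_indices.py`):

```
segmentation IoU vs ground truth: 1.000
 index      mean       sd  n_valid  n_undef
  NDAI    0.0452   0.1269     1594        0
  NARI    0.0452   0.1269     1594        0
   ARI    0.5757   1.3657     1594        0
  mACI    2.6353   0.6447     1594        0
  mARI    0.2878   0.6850     1594        0
   RGI    1.1338   0.2977     1594        0
```

The mean is the whole-scene index; the large sd reflects the two very
different discs. NDAI and NARI agree to numerical precision, as their
algebra requires. Evaluating all indices against true concentration on a
50-disc synthetic study (`examples/04_index_evaluation.py`):

```
      Index     Model       R2     RMSE    AIC         p
       NDAI quadratic   0.9986 0.003168 -567.5 1.791e-67
        RGI quadratic   0.9985 0.007198 -485.4 2.031e-67
       mARI quadratic    0.999  0.01368 -421.2 1.594e-71
        ARI quadratic    0.999  0.02739 -351.8 1.659e-71
       mACI quadratic   0.9944  0.03261 -334.3 1.347e-53
noise_dummy    linear 0.005214   0.9282 -1.456    0.6183
```

Lower AIC means a better calibration model: the green/red indices lead,
the NIR-based mACI trails (no chlorophyll correction), and the pure-noise
control ranks last.

A thin CLI wraps the same functions:

```sh
ndai calibrate gray.png --region 10,10,50,50 --band-role green
ndai index --band green=g.png --band red=r.png --band nir=n.png --indices NDAI,ARI
ndai simulate --n-samples 50 --seed 1 --out-dir sim/
ndai evaluate sim/evaluation_set.csv
```

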