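"""Leaf-disc index computation on a synthetic multispectral scene.

Two leaf discs with known anthocyanin levels (300 and 1400 µg g⁻¹ FW) are
rendered, segmented by Otsu thresholding on the NIR band, and all six
indices are computed over the plant pixels.
"""

from ndaikit import (
    ForwardModel,
    SceneSpec,
    SegmentationParams,
    compute_index,
    index_summary,
    mask_iou,
    render_multispectral,
    segment_stack,
)

spec = SceneSpec(
    layout="discs", n_objects=2, width=96, height=96,
    anthocyanin=[300.0, 1400.0], chlorophyll=[1.0, 1.0], seed=7,
)
stack, truth = render_multispectral(spec, ForwardModel(noise_sd=0.02))
mask = segment_stack(stack, SegmentationParams(method="otsu"))
print(f"segmentation IoU vs ground truth: {mask_iou(mask, truth.mask):.3f}")
print(f"{'index':>6}  {'mean':>8}  {'sd':>7}  {'n_valid':>7}  {'n_undef':>7}")
for name in ("NDAI", "NARI", "ARI", "mACI", "mARI", "RGI"):
    s = index_summary(compute_index(stack, name, mask))
    print(f"{name:>6}  {s.mean:8.4f}  {s.sd:7.4f}  {s.n_valid:7d}  {s.n_undefined:7d}")
# The mean is the whole-scene index; its sd measures anthocyanin
# heterogeneity (here: two discs with very different pigment levels).
# NDAI and NARI agree to numerical precision, as their algebra dictates.
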