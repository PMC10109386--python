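"""Gray-card exposure calibration.

A middle-gray card reflects 50% at every waveband, so a calibrated 8-bit
image should read 127. We render a card that was imaged too dark (mean
100), derive the correction factor 127/100, and apply it.
"""

import numpy as np

from ndaikit import BandImage, apply_gain, exposure_correction, measure_gray_region

card = BandImage(np.full((64, 64), 100, dtype=np.uint8), peak_nm=516, fwhm_nm=40)
measured = measure_gray_region(card, (0, 0, 64, 64))
cal = exposure_correction(measured, band_role="green")
corrected, n_clipped = apply_gain(card, cal.exposure_factor)

print(f"measured gray-card mean : {measured:.1f}")
print(f"exposure factor         : {cal.exposure_factor:.4f}")
print(f"corrected intensity     : {corrected.intensities[0, 0]}")
print(f"clipped pixels          : {n_clipped}")
# The corrected intensity is 127: the band is now on the common reflectance
# scale, directly comparable with bands imaged under other LEDs.
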