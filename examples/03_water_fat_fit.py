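"""Water-fat separation: PDFF and R2* maps from noiseless echo images.

Simulates the vial phantom at the 0.55 T protocol-1 echo times and fits the
magnitude signal model voxel by voxel (two-point Dixon initialisation, then
the multi-step Levenberg-Marquardt schedule).  On noiseless input the
per-vial mean PDFF reproduces the nominal values essentially exactly.
"""

import numpy as np

from llrpdff import FatSpectrum, fit_volume
from llrpdff.metrics import circular_roi_means
from llrpdff.phantom import echo_images, make_phantom, pdff_series_config
from llrpdff.presets import get_preset

spectrum = FatSpectrum.nine_peak_liver()
echoes = get_preset("protocol1_055T").echo_train()
config = pdff_series_config(shape=(2, 64, 64))
phantom = make_phantom(config)
images = echo_images(phantom, spectrum, echoes)

maps = fit_volume(images, spectrum)
rois = circular_roi_means(
    maps.pdff, [v.center for v in phantom.vials], [v.radius for v in phantom.vials]
)
print("nominal PDFF -> fitted ROI mean (middle slice):")
for vial, (mean, sd, n) in zip(phantom.vials, rois):
    print(f"  {vial.pdff_percent:5.1f}%  ->  {mean:8.4f}%   (sd {sd:.2e}, {n} voxels)")
print(f"\nR2* inside vials: {maps.r2s[phantom.pdff_map > 0].mean():.2f} 1/s "
      "(truth 40; noiseless fit is exact)")
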