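"""Simulate an accelerated phantom acquisition and reconstruct it.

Builds the digital fat-fraction vial phantom, simulates CAIPI-undersampled
(R = 4) multi-coil k-space with complex Gaussian noise, and compares the
zero-filled adjoint reconstruction with the unrolled locally low-rank
reconstruction (rank-2 SVT prior, six iterations) by PSNR/SSIM against the
noiseless ground truth.
"""

import numpy as np

from llrpdff import FatSpectrum, SenseSystem, make_coils, make_mask, make_phantom, simulate_kspace
from llrpdff.phantom import echo_images, pdff_series_config
from llrpdff.presets import get_preset
from llrpdff.unrolled import ReconConfig, evaluate_reconstruction, reconstruct, zero_filled

shape = (4, 64, 64)
spectrum = FatSpectrum.nine_peak_liver()
preset = get_preset("protocol1_055T")
echoes = preset.echo_train()

phantom = make_phantom(pdff_series_config(shape=shape))
reference = echo_images(phantom, spectrum, echoes)
coils = make_coils(shape, 8, seed=0)
mask = make_mask(shape[:2], preset.acceleration, pattern="caipi")
kspace = simulate_kspace(phantom, spectrum, echoes, coils, mask, noise_sd=0.05, seed=0)
print(f"k-space {kspace.data.shape}, sampled fraction {mask.sampled_fraction:.2f}")

system = SenseSystem(coils, mask)
zf = zero_filled(kspace, system)
recon = reconstruct(kspace, system, ReconConfig(denoiser="svt", lam=(1, 2, 4, 8, 8, 8)))

for name, img in [("zero-filled adjoint", zf), ("unrolled SVT (n=6)", recon)]:
    psnr, ssim = evaluate_reconstruction(img, reference)
    print(f"{name:22s} PSNR {psnr:6.2f} dB   SSIM {ssim:.3f}")
print("(the unrolled reconstruction should clearly beat the adjoint)")
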