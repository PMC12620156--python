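# llrpdff

Locally low-rank unrolled reconstruction and chemical-shift-encoded
water–fat quantification (PDFF, R2\*) for low-field multi-echo gradient-echo
MRI, with a digital fat–iron vial phantom simulator and the agreement /
repeatability statistics used to validate quantitative fat-fraction
measurements.

## Who this is for

Researchers developing or validating proton density fat fraction (PDFF)
pipelines at low field (0.55 T), where the water–fat chemical-shift
separation shrinks to ~80 Hz and the SNR penalty makes accelerated
multi-echo acquisitions noisy enough to bias the fat-fraction fit.  The
package lets you build the entire pipeline — k-space simulation, parallel
imaging reconstruction with a locally low-rank (LLR) prior, voxel-wise
water–fat fitting, and the statistics — with no scanner data.

## The model

A voxel's complex signal at echo time `TE_n` is

    M_n = (M_w + C_n M_f) · exp(−R2* · TE_n) · E_n,
    C_n = Σ_i w_i · exp(2πi Δf_i TE_n),

with water/fat amplitudes `M_w, M_f`, a single effective relaxation rate
`R2*`, a unit phasor `E_n` for system phase errors, and the multi-peak fat
dephasing coefficient `C_n` of a pre-calibrated spectrum (the packaged
nine-peak liver triglyceride model; main methylene peak at −3.40 ppm).
`PDFF = 100 · M_f / (M_f + M_w)`.

Reconstruction solves, per outer iteration `i`,

    m̂_i = argmin_m ‖S m − a‖² + (1/λ_i²) ‖m − z_{i−1}‖²,    z_0 = 0,

where `S` is the coil-sensitivity Cartesian encoding operator and the prior
`z_i` is built by projecting `m̂_i` onto per-patch spectral bases
(patch-wise SVD along the echo dimension, patch 1×3×3), denoising the
component images (rank-2 singular-value truncation, or a trained
convolutional network), and recasting them into the echo basis.  Because a
two-species signal with shared `R2*` has patch rank two, the leading
components carry the signal and the trailing ones mostly noise.

Fitting takes the echo magnitudes (which cancels `E_n`), initialises
`M_w, M_f` from a complex two-point Dixon solve on the echoes nearest
opposed/in phase, and runs a bounded multi-step Levenberg–Marquardt
schedule with a water–fat swap guard.

## Worked example

```python
from llrpdff import FatSpectrum, fat_coefficients
from llrpdff.fat_model import water_fat_separation_hz
from llrpdff.presets import get_preset

spectrum = FatSpectrum.nine_peak_liver()
print(water_fat_separation_hz(spectrum, 0.55))   # 79.6 Hz
print(water_fat_separation_hz(spectrum, 1.5))    # 217.1 Hz
echoes = get_preset("protocol1_055T").echo_train()
print(abs(fat_coefficients(spectrum, echoes)))
```

prints the ~80 Hz low-field separation and the fat dephasing magnitudes
`[0.960 0.876 0.791 0.766 0.797 0.830]` over the 0.55 T protocol-1 echo
train — a single dephasing cycle whose minimum (TE = 6.8 ms) is the
opposed-phase echo used to initialise the Dixon fit.  Fitting noiseless
echo images of the vial phantom recovers every nominal PDFF exactly:

```text
nominal PDFF -> fitted ROI mean (middle slice):
    0.0%  ->    0.0000%
   40.0%  ->   40.0000%
  100.0%  ->  100.0000%
R2* inside vials: 40.00 1/s (truth 40)
```

The `examples/` directory walks through each capability: the signal model
(`01`), simulation + reconstruction with PSNR/SSIM (`02`), water–fat
fitting (`03`), denoiser training (`04`), and the full repeatability study
(`05`).  A thin CLI mirrors the pipeline:

```bash
llrpdff simulate --out sim --grid 4,64,64 --seed 1
llrpdff reconstruct --input sim/kspace.h5 --out rec
llrpdff fit --echoes rec/echoes.nii.gz --out-prefix maps/phantom
llrpdff phantom-study --out study --seed 1234
```

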