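# Methods

This note documents the models, numerical choices and limitations of
`llrpdff`: a pipeline for simulating, reconstructing and quantifying
multi-echo gradient-echo acquisitions for liver fat (PDFF) and R2\*
mapping at low field.

## Signal model (`fat_model`)

The voxel signal is `M_n = (M_w + C_n M_f) exp(−R2* TE_n) E_n` with a
single effective relaxation rate for the water–fat mixture — the separate
water/fat rates of the general model are deliberately collapsed, which
improves the conditioning of the fit and is standard practice for
six-echo protocols.  The fat dephasing coefficient
`C_n = Σ w_i exp(2πi Δf_i TE_n)` uses a packaged nine-peak liver
triglyceride spectrum (`data/nine_peak_liver.tsv`, water reference
4.7 ppm, main methylene peak at −3.40 ppm, amplitudes normalised to 1).
Users may substitute any spectrum from a two-column text table.  The
gyromagnetic ratio is fixed at 42.577 MHz/T.

Sign conventions: chemical shifts are water-relative, negative upfield of
water.  Temperature correction moves the *water reference* by
−0.01 ppm/°C from 37 °C; each water-relative fat shift therefore changes
by `−(T−37)·(−0.01)` ppm, so the apparent water–fat separation grows below
body temperature (at 22 °C the methylene peak sits at −3.55 ppm).  This is
the physically consistent sign: fat resonances are temperature-stable
while the water line moves.

Consequences at 0.55 T: the water–methylene separation is ≈ 80 Hz
(217 Hz at 1.5 T), the in/opposed-phase cycle stretches to ~12.5 ms, and a
minimum-TE six-echo train samples only one fat dephasing cycle.

## Digital phantom and acquisition simulator (`phantom`)

The generator emulates a fat–iron calibration phantom: cylindrical vials of
prescribed PDFF (exact by construction in the truth maps) and R2\* inside a
spherical water bath (amplitude 1, R2\* 5 s⁻¹).  The default layout has 15
vials — eight fat-fraction vials (0–100 %, R2\* 40 s⁻¹) and seven iron
vials (PDFF 0, R2\* 30–210 s⁻¹); linearity studies use an 11-vial 0–100 %
series at R2\* 40 s⁻¹.  Sub-voxel vial shifts emulate repositioning
between scan repetitions.

Coil sensitivities follow a loop-array model: inverse-square magnitude
falloff from loop centres placed on one or two rings around the FOV (two
rings at different z for ≥ 6 coils, as in a 3-D body array) with geometric
phase, root-sum-of-squares normalised to 1.  The geometry was chosen by a
conditioning analysis: with eight coils and R = 4 CAIPI sampling the
median SENSE g-factor is ≈ 1.5 (95th percentile ≈ 2.1), typical of a real
receive array.  Purely Gaussian profiles were rejected because their
g-factors (median 2.5–5) made 1-D R = 4 unaliasing unrealistically noisy.

Encoding uses the centred orthonormal FFT over (z, y, x); undersampling
acts on (kz, ky) only.  Patterns: `uniform` (every R-th ky line), `caipi`
(ky lattice offset sheared across kz — the repeatability study default,
since the acquisitions it emulates are CAIPIRINHA-accelerated), and
seeded variable-density `random`.  Complex Gaussian noise
`σ(g1 + i g2)` is added on sampled locations only; with unit-RSS coils and
the orthonormal FFT, σ equals the noise SD of the fully sampled
coil-combined image, so "background SNR 20" means the bath's first-echo
magnitude is 20 σ.

## Regularized SENSE (`sense`)

Each outer iteration solves
`argmin ‖Sm − a‖² + (1/λ²)‖m − z‖²`, i.e. the normal equations
`(I + λ² S†S) m = λ² S†a + z` (this grouping reproduces both limits:
λ→0 returns the prior, λ→∞ the unregularized least-squares solution).
Three solver paths:

* fully sampled masks — exact voxelwise division (S†S is the squared coil
  RSS, diagonal in image domain);
* arbitrary Cartesian masks — Jacobi-preconditioned conjugate gradients on
  the Hermitian positive-definite normal operator, relative tolerance 1e-9,
  maximum 200 iterations (typically < 30 at the λ values used);
* small grids — a dense materialisation of S with cached SVD, used for
  exact solves and as the independent oracle in tests.

λ may be a scalar shared across echoes or per-echo; per-iteration values
are a config list.

## Locally low-rank machinery (`llr`)

For every voxel the 1×3×3 patch centred on it (clamped at the boundary) is
reshaped into a 6×9 matrix whose SVD gives an orthonormal spectral basis
`U` ordered by singular value; the voxel's coefficients are `U† m` and
back-projection applies `U`, so at full rank the pair is exactly unitary.
Column phases are fixed (first significant element real-positive) so bases
are deterministic across platforms; all-zero patches get identity bases.
The patch-averaged variant (`svt_denoise_patchwise`) reconstructs all
patch voxels from the truncated patch matrix and averages overlaps — the
classical LLR denoiser, used as baseline and oracle.  A two-species signal
with shared R2\* makes every patch matrix rank ≤ 2, so rank-2 truncation
is lossless on noiseless phantoms and removes roughly two thirds of white
noise on noisy ones.

## Unrolled reconstruction (`unrolled`)

Six alternations (default) of the regularized SENSE solve and the prior
update `z_i = U f(U† m̂_i)` with `z_0 = 0`; the image after the final solve
is returned.  Priors: `identity` (plain regularized SENSE), `svt`
(hard rank-2 truncation of the spectral components; soft shrinkage
available), `learned` (the network below).  Each volume is scaled by the
99th percentile of its adjoint reconstruction before the unroll and
rescaled after, making the network transferable across SNR levels.

The default λ schedule for the SVT prior is (1, 2, 4, 8, 8, 8) — a
continuation: strong regularization while the prior is still crude, data
consistency once it has stabilised.  It was calibrated once on validation
simulations and then frozen.  Flat small λ leaves residual aliasing
(the weakly-encoded modes converge as `1/(1+λ²σ²)` per iteration); a fully
geometric ramp ends so data-trusting that SENSE noise returns in full.

### The learned denoiser (`nn`) and its training

The denoiser is a compact pure-NumPy convolutional encoder–decoder:
three average-pooling stages, base width 32 doubling per stage, 3×3
convolutions with leaky-ReLU activations, 2×2 transposed-convolution
upsampling, skip connections, a 1×1 output convolution, a global residual
connection, and no dropout or normalisation layers.  Complex spectral
components are packed as 2r real channels.  Forward, backward and Adam are
hand-written, so training and inference are bit-deterministic for a seed.

Training is by prior matching: synthetic volumes (smooth random
"pseudo-anatomy" textures of water, fat and R2\*) are simulated fully
sampled, retrospectively undersampled at R = 4 with per-volume lattice
offsets plus noise, and the network learns to map the spectral projection
of the aliased first iterate to the projection of the fully sampled
reference in the same bases — supervised L1 loss, Adam, learning rate
1e-4, batch size 1, 60/20/20 train/validation/test split, validation loss
recorded before training and per epoch.  Training the denoiser against
fixed projections (rather than through the full unroll) keeps the
optimisation well-posed at small scale while preserving the contract that
matters downstream: the prior it produces improves the iterate it will be
applied to.

## Water–fat fitting (`dixon_fit`)

Echo-pair selection uses the main-peak-only model: the echoes whose
phasors are nearest −1 and +1 (ties to earlier echoes; a warning flag when
either is > 60° off target).  The complex two-point Dixon solve inverts the
2×2 system per voxel, estimates the common error phasor from the spatially
smoothed phase of the candidate water+fat sum (Gaussian σ 3 voxels,
in-plane), removes it, and re-solves; the magnitudes initialise the fit.

The magnitude fit minimises `Σ (|M_w + C_n M_f| e^{−R2* TE_n} − y_n)²`
with bounds `M_w, M_f ≥ 0`, `R2* ∈ [0, 500] s⁻¹`, using a batched
Levenberg–Marquardt (Marquardt diagonal damping, bound projection,
synchronous updates so voxel order is irrelevant).  The multi-step
schedule: (1) amplitudes only with R2\* clamped at 30 s⁻¹; (2) all three
parameters released — run both from the step-1 result and directly from
the raw initialisation, keeping the lower cost (the clamped step distorts
amplitudes when the true R2\* is far from 30 s⁻¹); (3) the same from the
water/fat-swapped initialisation, accepted only when its cost is below
0.1× the init-anchored cost.  The decisive-dominance margin is essential
at low field: the magnitude model is nearly swap-symmetric there, so a
plain lower-cost rule degenerates to a coin flip under noise and destroys
the disambiguation carried by the phase-informed initialisation, while
genuine wrong-basin rescues (cost ratio ≈ 0 on clean data) still pass.
A final local multi-start polish re-descends from ±0.5/±1 PDFF-point
perturbations, settling the adjacent shallow dips that the opposed-phase
cancellation creates in the cost valley.  A scalar scipy (bounded TRF)
implementation of the same schedule (`fit_voxel`) serves as an independent
cross-check of the batched fitter.

Identifiability limitation: as R2\* grows the decay flattens the echo
train and the magnitude model develops near-degenerate minima several
PDFF points apart (observed from ≈ 140 s⁻¹ at mid-range PDFF with the
0.55 T protocol TEs).  Noiseless recovery is machine-exact over
R2\* ∈ [0, 100] s⁻¹ — the low-field-relevant range — and that is the
domain on which the recovery guarantee is validated.

Noise behaviour: magnitude fitting inflates low-signal echoes (Rician
bias), which pushes PDFF estimates up near 0 % and down near 100 %; the
effect shrinks as reconstruction SNR improves, which is the motivation for
the LLR prior in the first place.  No explicit noise-bias correction is
applied.

## Statistics (`metrics`) and the study driver (`pipeline`)

ROI tables are pandas DataFrames (scan, rep, roi, mean, sd, n); phantom
ROIs are circles concentric with the vials at 80 % of the vial radius on
the middle slice.  Implemented: OLS regression with t-based 95 % CIs and a
Fisher-z interval for Pearson r (undefined at n ≤ 3; returned as NaN);
Bland–Altman bias and limits of agreement `bias ± 1.96 SD` with
`t·SD/√n` and `t·SD·√(3/n)` intervals; the repeatability coefficient
`RC = 1.96·√2·σ_w` with σ_w the root mean within-ROI variance across
repetitions (the QIBA convention; invariant to per-ROI offsets); the mean
peak-to-peak range across repetitions; and a one-sample t statistic on
paired differences (zero-variance differences are flagged exact).

`phantom_study` strings the stages together: k repetitions (fresh noise,
optional sub-voxel repositioning), reconstruction, fitting, ROI readout,
and all statistics in one report.  Default conditions: 0.55 T protocol 1
(TE 1.8–10.2 ms, R = 4), 64×64×8 grid, 11 vials 0–100 % PDFF at R2\*
40 s⁻¹, 8 coils, CAIPI sampling, background SNR 20, four repetitions,
rank-2 SVT prior.  At these conditions the regression of per-vial means
against nominal PDFF yields a slope within a few hundredths of unity and
r ≈ 0.99; the residual slope deficit (~0.03) is the Rician bias at the
achieved post-reconstruction SNR, since the rank-2 truncation retains
about a third of the per-voxel noise.

## What the simulations do and do not show

The generator reproduces the features that drive low-field PDFF error —
chemical-shift encoding with a realistic spectrum, parallel-imaging noise
amplification with realistic g-factors, Rician fit bias, vial geometry and
repositioning — but not gradient nonlinearity, eddy currents, motion, B0
inhomogeneity beyond a smooth optional phase field, partial volume
(rasterisation is binary), T1 weighting, or the spectrum of real anatomy.
Passing tests therefore validate the algorithms and their implementation,
not clinical performance on scanner data.

## Sizes and determinism

Default problem sizes (64×64×8 study grid, 32×32 training slices, 10-20
training volumes) are chosen so the full pipeline runs in minutes on one
CPU core.  Every random draw flows from an explicit seed (numpy
`default_rng`); reconstruction, training and simulation are reproducible
bit-for-bit for a given seed on a given platform.
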