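"""Unrolled locally low-rank reconstruction.

The reconstruction alternates n times (default 6) between a regularized
SENSE solve and a prior update: the current iterate is decomposed into local
spectral components (patchwise SVD along the echo dimension), the component
images are processed by a denoiser, and the result is recast into the echo
basis to serve as the prior z of the next solve, starting from z_0 = 0.

Three priors are available: ``identity`` (plain regularized SENSE),
``svt`` (classical singular-value truncation of the spectral components)
and ``learned`` (the NumPy encoder-decoder of :mod:`llrpdff.nn`, trained by
prior matching: it learns to map the spectral projection of an aliased,
noisy iterate to the projection of the fully sampled reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .fat_model import EchoTrain, FatSpectrum, MultiEchoImage
from .llr import PatchBasisField, SpectralProjection, back_project, local_bases, project
from .nn import Adam, UNet2d, l1_loss
from .phantom import (
    CoilSet,
    DigitalPhantom,
    KSpaceData,
    PhantomConfig,
    SamplingMask,
    echo_images,
    make_coils,
    make_mask,
    make_phantom,
    simulate_kspace,
)
from .sense import SenseSystem

__all__ = [
    "ReconConfig",
    "reconstruct",
    "zero_filled",
    "svt_prior",
    "evaluate_reconstruction",
    "make_training_pairs",
    "train",
    "TrainConfig",
]


@dataclass
class ReconConfig:
    """Settings of the unrolled iteration.

    ``lam`` is a scalar shared by all iterations or a length-n sequence of
    per-iteration regularization weights.  ``rank`` limits the spectral
    components handed to the denoiser (default: all echoes).
    """

    n_iter: int = 6
    patch_shape: tuple = (1, 3, 3)
    lam: float | tuple = 1.0
    denoiser: str = "identity"  # identity | svt | learned
    svt_rule: tuple = ("hard", 2)  # ("hard", k) or ("soft", tau)
    rank: int | None = None
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("need at least one iteration")
        if self.denoiser not in ("identity", "svt", "learned"):
            raise ValueError(f"unknown denoiser {self.denoiser!r}")

    def lam_at(self, i: int) -> float:
        if np.ndim(self.lam) == 0:
            return float(self.lam)
        return float(np.asarray(self.lam).ravel()[i])


def svt_prior(projection: SpectralProjection, rule=("hard", 2)) -> SpectralProjection:
    """Singular-value truncation of per-voxel spectral components.

    ``("hard", k)`` zeroes components beyond rank k.  ``("soft", tau)``
    shrinks each component by the factor implied by soft-thresholding the
    local singular values at ``tau * sigma_1``.
    """
    kind, value = rule
    coeff = projection.coefficients
    r = coeff.shape[0]
    if kind == "hard":
        k = int(value)
        if k > r:
            raise ValueError("rank cut exceeds the kept component count")
        out = coeff.copy()
        out[k:] = 0.0
    elif kind == "soft":
        s = np.moveaxis(projection.bases.singular_values[..., :r], -1, 0)
        thresh = float(value) * s[:1]
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(s > 0, np.maximum(s - thresh, 0.0) / np.where(s > 0, s, 1.0), 0.0)
        out = coeff * factor
    else:
        raise ValueError(f"unknown SVT rule {kind!r}")
    return SpectralProjection(out, projection.bases)


def _apply_network(projection: SpectralProjection, network: UNet2d) -> SpectralProjection:
    coeff = projection.coefficients  # (r, z, y, x)
    out = np.empty_like(coeff)
    for z in range(coeff.shape[1]):
        y = network.forward(UNet2d.pack(coeff[:, z]))
        if not np.all(np.isfinite(y)):
            raise FloatingPointError("network produced non-finite output")
        out[:, z] = UNet2d.unpack(y)
    return SpectralProjection(out, projection.bases)


def _denoise(projection: SpectralProjection, config: ReconConfig, network) -> SpectralProjection:
    if config.denoiser == "identity":
        return projection
    if config.denoiser == "svt":
        return svt_prior(projection, config.svt_rule)
    if network is None:
        raise ValueError("learned denoiser requires trained weights")
    return _apply_network(projection, network)


def reconstruct(
    kspace: KSpaceData,
    system: SenseSystem,
    config: ReconConfig | None = None,
    network: UNet2d | None = None,
) -> MultiEchoImage:
    """Run the unrolled reconstruction and return the final echo images.

    Iterates ``m_i = solve_regularized(a, z_{i-1}, lam_i)`` with ``z_0 = 0``
    and ``z_i = back_project(f(project(m_i)))``; returns the image after the
    final solve.  Deterministic given inputs and weights.
    """
    config = config or ReconConfig()
    a = np.asarray(kspace.data)
    scale = 1.0
    if config.normalize:
        zf = system.adjoint(a)
        scale = float(np.percentile(np.abs(zf), 99))
        if scale <= 0:
            scale = 1.0
        a = a / scale
    z: np.ndarray | float = 0.0
    m = None
    for i in range(config.n_iter):
        m = system.solve_regularized(a, prior=z, lam=config.lam_at(i))
        if i == config.n_iter - 1:
            break
        bases = local_bases(m, config.patch_shape, rank=config.rank)
        proj = project(m, bases)
        proj = _denoise(proj, config, network)
        z = back_project(proj)
    return MultiEchoImage(m * scale, kspace.echoes)


def zero_filled(kspace: KSpaceData, system: SenseSystem) -> MultiEchoImage:
    """Coil-combined adjoint (zero-filled) reconstruction baseline."""
    return MultiEchoImage(system.adjoint(kspace.data), kspace.echoes)


def evaluate_reconstruction(recon, reference) -> tuple:
    """(PSNR [dB], SSIM) of magnitude images against a noiseless reference.

    PSNR uses the reference peak; SSIM uses an 11-pixel Gaussian-weighted
    window with K1=0.01, K2=0.03 and the reference peak as data range,
    averaged over slices.
    """
    rec = np.abs(recon.data if hasattr(recon, "data") else np.asarray(recon))
    ref = np.abs(reference.data if hasattr(reference, "data") else np.asarray(reference))
    if rec.shape != ref.shape:
        raise ValueError("shapes differ")
    peak = float(ref.max())
    if peak <= 0:
        raise ValueError("reference has no signal")
    mse = float(np.mean((rec - ref) ** 2))
    psnr = float("inf") if mse == 0 else 10.0 * np.log10(peak**2 / mse)
    ssims = []
    for e in range(ref.shape[0]):
        for z in range(ref.shape[1]):
            ssims.append(
                structural_similarity(
                    ref[e, z],
                    rec[e, z],
                    data_range=peak,
                    gaussian_weights=True,
                    sigma=1.5,
                    win_size=11,
                    K1=0.01,
                    K2=0.03,
                )
            )
    return psnr, float(np.mean(ssims))


# ----------------------------------------------------------------------
# Desk-scale training: synthetic volumes, retrospective undersampling,
# prior-matching pairs.
# ----------------------------------------------------------------------


def _pseudo_anatomy(shape, rng) -> DigitalPhantom:
    """Smooth random water/fat/R2* textures standing in for anatomy.

    Sums of random Gaussian blobs produce smooth positive amplitude maps
    with spatially varying fat fraction and relaxation, masked to an
    elliptical support.
    """
    nz, ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")

    def blobs(n, lo, hi):
        f = np.zeros((ny, nx))
        for _ in range(n):
            cy, cx = rng.uniform(0, ny), rng.uniform(0, nx)
            w = rng.uniform(0.1, 0.35) * ny
            f += rng.uniform(0.2, 1.0) * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * w**2)
            )
        f = (f - f.min()) / max(np.ptp(f), 1e-12)
        return lo + (hi - lo) * f

    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    support2d = ((yy - cy) / (0.45 * ny)) ** 2 + ((xx - cx) / (0.45 * nx)) ** 2 <= 1.0
    water = np.empty(shape)
    fat = np.empty(shape)
    r2s = np.empty(shape)
    for z in range(nz):
        amp = blobs(6, 0.4, 1.0) * support2d
        frac = blobs(4, 0.0, rng.uniform(0.2, 0.9)) * support2d
        water[z] = amp * (1 - frac)
        fat[z] = amp * frac
        r2s[z] = blobs(3, 20.0, 80.0) * support2d
    total = water + fat
    pdff_map = np.where(total > 0, 100 * fat / np.where(total > 0, total, 1), 0.0)
    return DigitalPhantom(
        shape=shape,
        voxel_size_mm=(6.0, 2.5, 2.5),
        water_map=water,
        fat_map=fat,
        r2s_map=r2s,
        support=np.broadcast_to(support2d, shape).copy(),
        vials=[],
        pdff_map=pdff_map,
    )


def make_training_pairs(
    n_volumes: int,
    shape: tuple,
    echoes: EchoTrain,
    spectrum: FatSpectrum,
    n_coils: int = 8,
    acceleration: int = 4,
    noise_sd: float = 0.03,
    patch_shape=(1, 3, 3),
    rank: int | None = None,
    seed: int = 0,
):
    """Retrospectively undersampled prior-matching training samples.

    Each synthetic volume is simulated fully sampled, then undersampled at
    the requested acceleration with a per-volume ky lattice offset (varying
    patterns) plus complex Gaussian noise.  For every slice the sample is
    (spectral projection of the aliased first iterate, projection of the
    fully sampled reference in the same bases), packed as real channels.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for v in range(n_volumes):
        phan = _pseudo_anatomy(shape, rng)
        ref = echo_images(phan, spectrum, echoes).data
        coils = make_coils(shape, n_coils, seed=rng)
        mask_arr = np.zeros(shape[:2], bool)
        offset = int(rng.integers(acceleration))
        mask_arr[:, offset::acceleration] = True
        mask = SamplingMask(mask_arr, acceleration, "uniform-offset")
        system = SenseSystem(coils, mask)
        ksp = simulate_kspace(
            phan, spectrum, echoes, coils, mask, noise_sd=noise_sd, seed=rng
        )
        scale = float(np.percentile(np.abs(system.adjoint(ksp.data)), 99)) or 1.0
        m1 = system.solve_regularized(ksp.data / scale, prior=0.0, lam=1.0)
        bases = local_bases(m1, patch_shape, rank=rank)
        x_proj = project(m1, bases).coefficients
        y_proj = project(ref / scale, bases).coefficients
        for z in range(shape[0]):
            samples.append((UNet2d.pack(x_proj[:, z]), UNet2d.pack(y_proj[:, z])))
    return samples


@dataclass
class TrainConfig:
    epochs: int = 10
    learning_rate: float = 1e-4
    base_features: int = 32
    n_pools: int = 3
    val_fraction: float = 0.2
    test_fraction: float = 0.2


def train(training_pairs, config: TrainConfig | None = None, seed: int = 0):
    """Train the denoiser on (input, target) channel-packed slice pairs.

    Supervised L1 loss, Adam, batch size 1.  The pair list is split
    60/20/20 into train/validation/test; the validation loss is evaluated
    before training (epoch 0) and after every epoch.  Returns
    ``(network, history)`` with ``history`` holding per-epoch mean train
    loss and validation loss.  Deterministic for a fixed seed.
    """
    config = config or TrainConfig()
    if not training_pairs:
        raise ValueError("no training data")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(training_pairs))
    n_val = max(1, int(round(config.val_fraction * len(idx))))
    n_test = max(1, int(round(config.test_fraction * len(idx))))
    val_idx = idx[:n_val]
    test_idx = idx[n_val : n_val + n_test]
    train_idx = idx[n_val + n_test :]
    if train_idx.size == 0:
        raise ValueError("too few samples to form a training split")

    channels = training_pairs[0][0].shape[0]
    net = UNet2d(channels, config.base_features, config.n_pools, seed=seed)
    opt = Adam(net, lr=config.learning_rate)

    def mean_loss(indices):
        losses = []
        for i in indices:
            x, y = training_pairs[i]
            losses.append(l1_loss(net.forward(x), y)[0])
        return float(np.mean(losses))

    history = {"train_loss": [], "val_loss": [mean_loss(val_idx)]}
    for _ in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_losses = []
        for i in order:
            x, y = training_pairs[i]
            pred = net.forward(x)
            loss, grad = l1_loss(pred, y)
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged (non-finite loss)")
            net.zero_grad()
            net.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(mean_loss(val_idx))
    history["test_loss"] = mean_loss(test_idx)
    history["splits"] = {
        "train": train_idx.tolist(),
        "val": val_idx.tolist(),
        "test": test_idx.tolist(),
    }
    return net, history
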