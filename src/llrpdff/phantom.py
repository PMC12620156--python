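"""Digital fat-iron vial phantom and multi-coil Cartesian k-space simulator.

The generator stands in for a physical fat-fraction/iron calibration phantom:
cylindrical vials of known PDFF (0-100 %) and R2* immersed in a spherical
water bath, imaged with smooth complex coil sensitivities, regular Cartesian
undersampling along ky (optionally with a kz shear) and additive complex
Gaussian k-space noise.  All randomness is seeded.

Conventions (package-wide): arrays are ordered (coil, echo, z, y, x);
k-space uses the centred, orthonormal discrete Fourier transform over the
spatial axes; undersampling acts on (kz, ky) only, kx is fully sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fat_model import EchoTrain, FatSpectrum, MultiEchoImage, fat_coefficients

__all__ = [
    "Vial",
    "DigitalPhantom",
    "PhantomConfig",
    "CoilSet",
    "SamplingMask",
    "KSpaceData",
    "make_phantom",
    "pdff_series_config",
    "make_coils",
    "make_mask",
    "simulate_kspace",
    "echo_images",
    "fftc",
    "ifftc",
]


def fftc(x: np.ndarray, axes=(-3, -2, -1)) -> np.ndarray:
    """Centred orthonormal FFT (DC at the array centre)."""
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifftc(x: np.ndarray, axes=(-3, -2, -1)) -> np.ndarray:
    """Inverse of :func:`fftc`."""
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


@dataclass(frozen=True)
class Vial:
    """Cylindrical vial: centre (y, x) in voxels, radius in voxels."""

    center: tuple
    radius: float
    pdff_percent: float
    r2s: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pdff_percent <= 100.0:
            raise ValueError("vial PDFF must be in [0, 100] %")
        if self.r2s < 0:
            raise ValueError("vial R2* must be non-negative")


@dataclass
class PhantomConfig:
    shape: tuple = (8, 64, 64)  # (z, y, x)
    voxel_size_mm: tuple = (6.0, 2.5, 2.5)
    vials: list | None = None  # None -> default 15-vial preset
    bath_amplitude: float = 1.0
    bath_r2s: float = 5.0
    bath_radius_fraction: float = 0.94
    phase_error_order: int = 0  # 0 = no per-echo phase-error field


@dataclass
class DigitalPhantom:
    """Voxelwise ground-truth maps on a (z, y, x) grid."""

    shape: tuple
    voxel_size_mm: tuple
    water_map: np.ndarray
    fat_map: np.ndarray
    r2s_map: np.ndarray
    support: np.ndarray  # bath + vials
    vials: list
    pdff_map: np.ndarray
    phase_fields: np.ndarray | None = None  # (E, z, y, x) unit phasors


@dataclass
class CoilSet:
    """Complex sensitivity map per coil, (coil, z, y, x)."""

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return int(self.maps.shape[0])

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass
class SamplingMask:
    """Boolean (kz, ky) mask with acceleration bookkeeping."""

    mask: np.ndarray  # (z, y) bool
    acceleration: int
    pattern: str
    calibration_lines: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a (kz, ky) boolean array")

    @property
    def sampled_fraction(self) -> float:
        return float(self.mask.mean())

    def achieved_acceleration(self) -> float:
        """Acceleration of the undersampled region (calibration excluded).

        The fully sampled calibration block inflates the sampled fraction, so
        nominal-R accounting is done on the lattice portion of ky only.
        """
        nz, ny = self.mask.shape
        if self.calibration_lines > 0:
            lo = (ny - self.calibration_lines) // 2
            hi = lo + self.calibration_lines
            keep = np.ones(ny, bool)
            keep[lo:hi] = False
            sub = self.mask[:, keep]
        else:
            sub = self.mask
        frac = sub.mean()
        return float(1.0 / frac) if frac > 0 else float("inf")


@dataclass
class KSpaceData:
    """Acquired multi-coil multi-echo samples, (coil, echo, z, y, x)."""

    data: np.ndarray
    mask: SamplingMask
    echoes: EchoTrain
    noise_sd: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError("expected (coil, echo, z, y, x) k-space")


def _default_vials(shape: tuple) -> list:
    """Fifteen vials echoing a fat-iron calibration phantom layout.

    Eight fat-fraction vials span 0-100 % PDFF at a common moderate R2*;
    seven iron vials hold 0 % PDFF with increasing R2*.
    """
    nz, ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    radius = min(ny, nx) / 14.0
    ff_values = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 70.0, 100.0]
    iron_r2s = [30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0]
    vials = []
    ring_r = min(ny, nx) * 0.33
    for k, ff in enumerate(ff_values):
        ang = 2 * np.pi * k / len(ff_values)
        vials.append(
            Vial(
                center=(cy + ring_r * np.sin(ang), cx + ring_r * np.cos(ang)),
                radius=radius,
                pdff_percent=ff,
                r2s=40.0,
            )
        )
    inner_r = min(ny, nx) * 0.155
    for k, r2s in enumerate(iron_r2s):
        if k == 0:
            center = (cy, cx)
        else:
            ang = 2 * np.pi * (k - 1) / (len(iron_r2s) - 1) + np.pi / 6
            center = (cy + inner_r * np.sin(ang), cx + inner_r * np.cos(ang))
        vials.append(Vial(center=center, radius=radius, pdff_percent=0.0, r2s=r2s))
    return vials


def pdff_series_config(
    shape: tuple = (8, 64, 64),
    pdff_values=tuple(range(0, 101, 10)),
    r2s: float = 40.0,
    **kwargs,
) -> PhantomConfig:
    """Config with one vial per requested PDFF value, laid out on a ring.

    The default is the eleven-step 0,10,...,100 % series used for linearity
    studies, all vials at a common R2*.
    """
    nz, ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    n = len(pdff_values)
    radius = min(ny, nx) / 13.0
    vials = []
    ring_r = min(ny, nx) * 0.33
    for k, ff in enumerate(pdff_values):
        if k == 0:
            center = (cy, cx)
        else:
            ang = 2 * np.pi * (k - 1) / (n - 1)
            center = (cy + ring_r * np.sin(ang), cx + ring_r * np.cos(ang))
        vials.append(Vial(center, radius, float(ff), float(r2s)))
    return PhantomConfig(shape=shape, vials=vials, **kwargs)


def make_phantom(
    config: PhantomConfig, center_shift=(0.0, 0.0), rng: np.random.Generator | None = None
) -> DigitalPhantom:
    """Rasterise the vial phantom into ground-truth (M_w, M_f, R2*) maps.

    ``center_shift`` translates every vial by a (y, x) sub-voxel offset,
    emulating phantom repositioning between scan repetitions.  Inside each
    vial ``M_f / (M_f + M_w)`` equals the requested PDFF exactly.
    """
    nz, ny, nx = config.shape
    vials = config.vials if config.vials is not None else _default_vials(config.shape)
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    bath_r = min(ny, nx) / 2.0 * config.bath_radius_fraction
    bath = (yy - cy) ** 2 + (xx - cx) ** 2 <= bath_r**2

    water = np.where(bath, config.bath_amplitude, 0.0).astype(float)
    fat = np.zeros(config.shape)
    r2s = np.where(bath, config.bath_r2s, 0.0).astype(float)
    pdff_map = np.zeros(config.shape)

    occupied = np.zeros(config.shape, bool)
    for v in vials:
        vy = v.center[0] + center_shift[0]
        vx = v.center[1] + center_shift[1]
        inside = (yy - vy) ** 2 + (xx - vx) ** 2 <= v.radius**2
        if not inside.any():
            raise ValueError(f"vial at {v.center} lies outside the grid")
        if (inside & occupied).any():
            raise ValueError("vials overlap")
        occupied |= inside
        frac = v.pdff_percent / 100.0
        water[inside] = v.amplitude * (1.0 - frac)
        fat[inside] = v.amplitude * frac
        r2s[inside] = v.r2s
        pdff_map[inside] = v.pdff_percent

    support = bath | occupied
    phase_fields = None
    if config.phase_error_order > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        phase_fields = _smooth_phase_fields(
            config.shape, n_echoes=6, order=config.phase_error_order, rng=rng
        )
    return DigitalPhantom(
        shape=config.shape,
        voxel_size_mm=config.voxel_size_mm,
        water_map=water,
        fat_map=fat,
        r2s_map=r2s,
        support=support,
        vials=list(vials),
        pdff_map=pdff_map,
        phase_fields=phase_fields,
    )


def _smooth_phase_fields(
    shape: tuple, n_echoes: int, order: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit-magnitude smooth polynomial phase per echo, growing with echo."""
    nz, ny, nx = shape
    y = np.linspace(-1, 1, ny)[None, :, None]
    x = np.linspace(-1, 1, nx)[None, None, :]
    fields = np.empty((n_echoes, nz, ny, nx), complex)
    for n in range(n_echoes):
        phase = np.zeros((nz, ny, nx))
        for p in range(order + 1):
            for q in range(order + 1 - p):
                phase = phase + rng.normal(scale=0.5) * (y**p) * (x**q)
        fields[n] = np.exp(1j * phase * (n + 1) / n_echoes)
    return fields


def echo_images(
    phantom: DigitalPhantom, spectrum: FatSpectrum, echoes: EchoTrain
) -> MultiEchoImage:
    """Noiseless complex echo images of the phantom, (echo, z, y, x)."""
    coeffs = fat_coefficients(spectrum, echoes)  # (E,)
    te = echoes.echo_times
    mw = phantom.water_map[None]
    mf = phantom.fat_map[None]
    decay = np.exp(-phantom.r2s_map[None] * te[:, None, None, None])
    imgs = (mw + coeffs[:, None, None, None] * mf) * decay
    if phantom.phase_fields is not None:
        e = phantom.phase_fields
        if e.shape[0] != echoes.n_echoes:
            raise ValueError("phase-error field echo count mismatch")
        imgs = imgs * e
    return MultiEchoImage(imgs.astype(complex), echoes)


def make_coils(
    shape: tuple, n_coils: int, seed: int | np.random.Generator = 0
) -> CoilSet:
    """Loop-array complex coil maps, root-sum-of-squares normalised to 1.

    Coils are modelled as receive loops placed on one or two rings around
    the FOV (two rings at different z when the coil count and slice count
    allow, as in a 3D body array): inverse-square magnitude falloff from the
    loop centre and a geometric phase, plus a small random per-coil phase
    offset.  A single coil is a constant (uniform) map.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    nz, ny, nx = shape
    if n_coils == 1:
        return CoilSet(np.ones((1, nz, ny, nx), complex))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.linspace(-1, 1, nz)[:, None, None] if nz > 1 else np.zeros((1, 1, 1))
    y = np.linspace(-1, 1, ny)[None, :, None]
    x = np.linspace(-1, 1, nx)[None, None, :]
    n_rings = 2 if (n_coils >= 6 and n_coils % 2 == 0 and nz > 1) else 1
    per_ring = n_coils // n_rings
    radius, z_weight = 1.15, 2.0
    maps = np.empty((n_coils, nz, ny, nx), complex)
    for c in range(n_coils):
        ring, k = divmod(c, per_ring)
        ang = 2 * np.pi * k / per_ring + ring * np.pi / per_ring
        cy, cx = radius * np.sin(ang), radius * np.cos(ang)
        cz = (-0.7 + 1.4 * ring / (n_rings - 1)) if n_rings > 1 else 0.0
        d2 = (y - cy) ** 2 + (x - cx) ** 2 + z_weight * (z - cz) ** 2
        phase = np.arctan2(y - cy, x - cx) + 0.5 * ang + rng.normal(scale=0.3)
        maps[c] = (1.0 / d2) * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return CoilSet(maps / rss[None])


def make_mask(
    shape: tuple,
    acceleration: int,
    pattern: str = "uniform",
    calibration_lines: int = 0,
    seed: int | None = None,
) -> SamplingMask:
    """Cartesian (kz, ky) sampling mask.

    Patterns: ``uniform`` (every R-th ky line), ``caipi`` (ky lattice with a
    kz-dependent shear of the lattice offset) and ``random`` (variable-density
    random ky lines, denser near the centre, seeded).  A centred block of
    ``calibration_lines`` ky lines is always fully sampled.
    """
    nz, ny = shape[-2], shape[-1]
    if acceleration not in (1, 2, 3, 4, 6):
        raise ValueError("acceleration must be one of {1, 2, 3, 4, 6}")
    if acceleration > ny:
        raise ValueError("acceleration exceeds the phase-encode count")
    mask = np.zeros((nz, ny), bool)
    if acceleration == 1 or pattern == "full":
        mask[:] = True
    elif pattern == "uniform":
        mask[:, ::acceleration] = True
    elif pattern == "caipi":
        for z in range(nz):
            mask[z, (z % acceleration) :: acceleration] = True
    elif pattern == "random":
        if seed is None:
            raise ValueError("random pattern requires a seed")
        rng = np.random.default_rng(seed)
        n_lines = max(1, round(ny / acceleration))
        ky = np.arange(ny)
        weight = np.exp(-(((ky - (ny - 1) / 2) / (0.35 * ny)) ** 2))
        chosen = rng.choice(ny, size=n_lines, replace=False, p=weight / weight.sum())
        mask[:, chosen] = True
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    if calibration_lines > 0:
        lo = (ny - calibration_lines) // 2
        mask[:, lo : lo + calibration_lines] = True
    return SamplingMask(mask, acceleration, pattern, calibration_lines)


def simulate_kspace(
    phantom: DigitalPhantom,
    spectrum: FatSpectrum,
    echoes: EchoTrain,
    coils: CoilSet,
    mask: SamplingMask,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> KSpaceData:
    """Forward-simulate undersampled multi-coil k-space.

    Per coil c and echo n: ``k = mask * F(S_c * M_n) + mask * sigma*(g1+i g2)``
    with standard-normal g and the centred orthonormal FFT.  Unsampled
    entries are exactly zero.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    imgs = echo_images(phantom, spectrum, echoes).data  # (E, z, y, x)
    if coils.maps.shape[1:] != imgs.shape[1:]:
        raise ValueError("coil maps do not match the phantom grid")
    if mask.mask.shape != imgs.shape[1:3]:
        raise ValueError("mask does not match the (kz, ky) grid")
    coil_imgs = coils.maps[:, None] * imgs[None]  # (C, E, z, y, x)
    ksp = fftc(coil_imgs)
    m = mask.mask[None, None, :, :, None]
    ksp = ksp * m
    if noise_sd > 0:
        rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )
        noise = noise_sd * (
            rng.standard_normal(ksp.shape) + 1j * rng.standard_normal(ksp.shape)
        )
        ksp = ksp + noise * m
    return KSpaceData(
        ksp,
        mask,
        echoes,
        noise_sd,
        seed=seed if isinstance(seed, int) else None,
    )
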