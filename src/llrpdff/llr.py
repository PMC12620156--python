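"""Locally low-rank machinery: patch SVD bases along the echo dimension.

For every spatial position a small in-plane patch (default 1x3x3 in
(z, y, x)) is reshaped into an E x N_x matrix whose columns are the echo
vectors of the patch voxels.  Its left singular vectors form a local
spectral basis: for a two-species (water/fat) signal sharing R2* the matrix
has effective rank two, so the leading components carry the signal and the
trailing ones mostly noise.  Projection applies U^H per voxel (using the
basis of the patch centred on that voxel); back-projection applies U, so at
full rank the pair is exactly unitary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PatchBasisField",
    "SpectralProjection",
    "extract_patch_matrix",
    "patch_matrices",
    "scatter_patch_matrices",
    "local_bases",
    "project",
    "back_project",
    "svt_denoise_patchwise",
]


@dataclass
class PatchBasisField:
    """Per-voxel spectral bases U of shape (z, y, x, E, r) plus singular values."""

    bases: np.ndarray  # (z, y, x, E, r)
    singular_values: np.ndarray  # (z, y, x, r_full)
    patch_shape: tuple
    rank: int

    @property
    def n_echoes(self) -> int:
        return int(self.bases.shape[-2])


@dataclass
class SpectralProjection:
    """Per-voxel spectral coefficients, (r, z, y, x), tied to its basis field."""

    coefficients: np.ndarray
    bases: PatchBasisField

    @property
    def rank(self) -> int:
        return int(self.coefficients.shape[0])


def _clamped_centers(n: int, w: int) -> np.ndarray:
    """Map voxel index to the index of the patch window containing it.

    Windows of width w exist at positions 0..n-w; a centre is clamped so the
    patch stays inside the grid (edge voxels reuse the nearest interior
    window).
    """
    half = (w - 1) // 2
    return np.clip(np.arange(n) - half, 0, n - w)


def patch_matrices(image: np.ndarray, patch_shape=(1, 3, 3)) -> np.ndarray:
    """All stride-1 patch matrices, one per voxel, shape (z, y, x, E, N_x).

    The patch assigned to a voxel is the one centred on it, shifted inward
    at the grid boundary.
    """
    image = np.asarray(image)
    if image.ndim != 4:
        raise ValueError("expected an (echo, z, y, x) image")
    e, nz, ny, nx = image.shape
    pz, py, px = patch_shape
    if pz > nz or py > ny or px > nx:
        raise ValueError("patch larger than the grid")
    win = sliding_window_view(image, (pz, py, px), axis=(1, 2, 3))
    # win: (E, nz-pz+1, ny-py+1, nx-px+1, pz, py, px)
    iz = _clamped_centers(nz, pz)
    iy = _clamped_centers(ny, py)
    ix = _clamped_centers(nx, px)
    win = win[:, iz[:, None, None], iy[None, :, None], ix[None, None, :]]
    return np.moveaxis(win.reshape(e, nz, ny, nx, pz * py * px), 0, 3)


def extract_patch_matrix(
    image: np.ndarray, center: tuple, patch_shape=(1, 3, 3)
) -> np.ndarray:
    """The E x N_x matrix of the patch centred at ``center`` (z, y, x)."""
    image = np.asarray(image)
    e, nz, ny, nx = image.shape
    pz, py, px = patch_shape
    if pz > nz or py > ny or px > nx:
        raise ValueError("patch larger than the grid")
    cz, cy, cx = center
    z0 = int(np.clip(cz - (pz - 1) // 2, 0, nz - pz))
    y0 = int(np.clip(cy - (py - 1) // 2, 0, ny - py))
    x0 = int(np.clip(cx - (px - 1) // 2, 0, nx - px))
    patch = image[:, z0 : z0 + pz, y0 : y0 + py, x0 : x0 + px]
    return patch.reshape(e, pz * py * px)


def scatter_patch_matrices(
    patches: np.ndarray, image_shape: tuple, patch_shape=(1, 3, 3)
) -> np.ndarray:
    """Adjoint of :func:`patch_matrices` followed by overlap-count averaging.

    ``scatter(patch_matrices(m)) == m`` exactly (partition of unity).
    """
    e, nz, ny, nx = image_shape
    pz, py, px = patch_shape
    accum = np.zeros(image_shape, dtype=patches.dtype)
    count = np.zeros((nz, ny, nx))
    iz = _clamped_centers(nz, pz)
    iy = _clamped_centers(ny, py)
    ix = _clamped_centers(nx, px)
    pat = np.moveaxis(patches, 3, 0).reshape(e, nz, ny, nx, pz, py, px)
    for dz in range(pz):
        for dy in range(py):
            for dx in range(px):
                contrib = pat[..., dz, dy, dx]  # (E, nz, ny, nx) per centre
                np.add.at(
                    accum,
                    (
                        slice(None),
                        (iz + dz)[:, None, None],
                        (iy + dy)[None, :, None],
                        (ix + dx)[None, None, :],
                    ),
                    contrib,
                )
                np.add.at(
                    count,
                    (
                        (iz + dz)[:, None, None],
                        (iy + dy)[None, :, None],
                        (ix + dx)[None, None, :],
                    ),
                    1.0,
                )
    return accum / count[None]


def _fix_column_phase(u: np.ndarray) -> np.ndarray:
    """Make the first significant element of each singular vector real-positive.

    Batched over leading axes; makes bases deterministic across platforms.
    """
    mags = np.abs(u)
    tol = 1e-12
    first = np.argmax(mags > tol, axis=-2)  # (..., r) index of first nonzero
    pivot = np.take_along_axis(u, first[..., None, :], axis=-2)[..., 0, :]
    phase = np.where(np.abs(pivot) > tol, pivot / np.abs(np.where(np.abs(pivot) > tol, pivot, 1)), 1.0)
    return u * np.conj(phase)[..., None, :]


def local_bases(
    image: np.ndarray, patch_shape=(1, 3, 3), rank: int | None = None
) -> PatchBasisField:
    """Left singular vectors of every patch matrix, ordered by singular value.

    ``rank`` keeps the leading r columns (default: all E, no truncation).
    All-zero patches get the first r columns of the identity.
    """
    image = np.asarray(image, complex)
    e = image.shape[0]
    r = e if rank is None else int(rank)
    if r > e:
        raise ValueError("rank cannot exceed the echo count")
    mats = patch_matrices(image, patch_shape)  # (z, y, x, E, Nx)
    if e > mats.shape[-1]:
        raise ValueError("patch has fewer voxels than echoes; enlarge the patch")
    u, s, _ = np.linalg.svd(mats, full_matrices=False)
    u = u[..., :e]  # (z, y, x, E, E)
    dead = s[..., 0] <= 1e-300  # all-zero patches
    if dead.any():
        u[dead] = np.eye(e, dtype=complex)
    u = _fix_column_phase(u)
    return PatchBasisField(
        bases=u[..., :r],
        singular_values=s,
        patch_shape=tuple(patch_shape),
        rank=r,
    )


def project(image: np.ndarray, bases: PatchBasisField) -> SpectralProjection:
    """Per-voxel spectral coefficients ``U^H m`` (unitary analysis)."""
    image = np.asarray(image, complex)
    if image.shape[0] != bases.n_echoes:
        raise ValueError("echo count does not match the basis field")
    if image.shape[1:] != bases.bases.shape[:3]:
        raise ValueError("grid does not match the basis field")
    coeff = np.einsum("zyxer,ezyx->rzyx", np.conj(bases.bases), image)
    return SpectralProjection(coeff, bases)


def back_project(
    projection: SpectralProjection, bases: PatchBasisField | None = None
) -> np.ndarray:
    """Per-voxel synthesis ``U p``; exact inverse of project at full rank."""
    b = projection.bases if bases is None else bases
    if b is not projection.bases:
        if b.bases.shape != projection.bases.bases.shape:
            raise ValueError("basis field does not match the projection")
    if projection.coefficients.shape[0] != b.bases.shape[-1]:
        raise ValueError("component count does not match the basis rank")
    return np.einsum("zyxer,rzyx->ezyx", b.bases, projection.coefficients)


def svt_denoise_patchwise(
    image: np.ndarray,
    patch_shape=(1, 3, 3),
    rank: int | None = 2,
    soft_fraction: float | None = None,
) -> np.ndarray:
    """Classical patchwise singular-value-truncation denoiser.

    Every stride-1 patch matrix is SVD-truncated (hard rank cut and/or soft
    shrinkage by ``soft_fraction * sigma_1``) and the overlapping results are
    averaged back into the image.  Serves as the non-learned baseline prior.
    """
    image = np.asarray(image, complex)
    mats = patch_matrices(image, patch_shape)
    u, s, vh = np.linalg.svd(mats, full_matrices=False)
    if soft_fraction is not None:
        thresh = soft_fraction * s[..., :1]
        s = np.maximum(s - thresh, 0.0)
    if rank is not None:
        s = s.copy()
        s[..., rank:] = 0.0
    rec = np.einsum("zyxer,zyxr,zyxrn->zyxen", u, s, vh)
    return scatter_patch_matrices(rec, image.shape, patch_shape)
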