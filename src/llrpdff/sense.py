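"""Coil-sensitivity encoding operator and the regularized SENSE solve.

The forward operator maps an echo-image stack m to undersampled multi-coil
k-space, ``S m = mask * F(s_c m)``.  Each outer iteration of the unrolled
reconstruction solves the proximal problem

    m = argmin ||S m - a||^2 + (1/lambda^2) ||m - z||^2

whose unique minimiser satisfies the normal equations
``(I + lambda^2 S'S) m = lambda^2 S'a + z``.  Three solver paths are
provided: an exact voxelwise formula when the mask is fully sampled (S'S is
then diagonal: the coil RSS squared), a Jacobi-preconditioned conjugate
gradient for arbitrary Cartesian masks, and a dense SVD solve for small
systems that can be materialised explicitly (also the test oracle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import CoilSet, SamplingMask, fftc, ifftc

__all__ = ["SenseSystem", "estimate_coils_from_calibration"]


@dataclass
class _SolveInfo:
    method: str
    iterations: int
    residual: float


class SenseSystem:
    """Encoding operator S for a fixed coil set and sampling mask.

    Images are (echo, z, y, x); k-space is (coil, echo, z, y, x).  The same
    mask is applied to every echo.  ``lam`` may be a scalar (shared across
    echoes) or a length-E vector (per-echo regularization).
    """

    def __init__(self, coils: CoilSet, mask: SamplingMask):
        self.coils = coils
        self.mask = mask
        self._rss2 = coils.rss() ** 2  # (z, y, x)
        self._fully_sampled = bool(mask.mask.all())
        self._svd_cache: dict | None = None
        self.last_info: _SolveInfo | None = None

    # -- operator --------------------------------------------------------

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Forward: ``mask * F(s_c * m)`` per coil; linear in the image."""
        image = np.asarray(image)
        if image.shape[1:] != self.coils.maps.shape[1:]:
            raise ValueError("image grid does not match the coil maps")
        coil_imgs = self.coils.maps[:, None] * image[None]
        ksp = fftc(coil_imgs)
        return ksp * self.mask.mask[None, None, :, :, None]

    def adjoint(self, kspace: np.ndarray) -> np.ndarray:
        """Adjoint: ``sum_c conj(s_c) F^-1(mask * k)``."""
        ksp = np.asarray(kspace) * self.mask.mask[None, None, :, :, None]
        coil_imgs = ifftc(ksp)
        return np.sum(np.conj(self.coils.maps)[:, None] * coil_imgs, axis=0)

    def normal(self, image: np.ndarray) -> np.ndarray:
        """S'S applied to an image."""
        return self.adjoint(self.apply(image))

    # -- solves ----------------------------------------------------------

    def solve_regularized(
        self,
        data: np.ndarray,
        prior: np.ndarray | float = 0.0,
        lam: float | np.ndarray = 1.0,
        method: str = "auto",
        tol: float = 1e-9,
        maxiter: int = 200,
    ) -> np.ndarray:
        """Solve ``(I + lam^2 S'S) m = lam^2 S'a + z``.

        ``lam -> 0`` returns the prior; large ``lam`` approaches the
        unregularized least-squares solution.  ``lam`` must be finite and
        non-negative.
        """
        lam = np.asarray(lam, dtype=float)
        if np.any(lam < 0) or not np.all(np.isfinite(lam)):
            raise ValueError("lambda must be finite and non-negative")
        lam2 = lam**2
        if lam2.ndim == 1:  # per-echo
            lam2 = lam2[:, None, None, None]
        rhs = lam2 * self.adjoint(data) + prior
        if method == "auto":
            method = "diag" if self._fully_sampled else "cg"
        if method == "diag":
            if not self._fully_sampled:
                raise ValueError("diagonal solve requires a fully sampled mask")
            out = rhs / (1.0 + lam2 * self._rss2[None])
            self.last_info = _SolveInfo("diag", 0, 0.0)
            return out
        if method == "dense":
            return self._solve_dense(rhs, lam2)
        if method == "cg":
            return self._solve_cg(rhs, lam2, tol=tol, maxiter=maxiter)
        raise ValueError(f"unknown method {method!r}")

    def _solve_cg(self, rhs, lam2, tol, maxiter):
        """Preconditioned CG on the Hermitian PD normal operator."""
        precond = 1.0 / (1.0 + lam2 * self._rss2[None])

        def A(x):
            return x + lam2 * self.normal(x)

        x = np.zeros_like(rhs)
        r = rhs - A(x)
        z = precond * r
        p = z.copy()
        rz = np.vdot(r, z).real
        rhs_norm = np.linalg.norm(rhs)
        it = 0
        for it in range(1, maxiter + 1):
            Ap = A(p)
            alpha = rz / np.vdot(p, Ap).real
            x = x + alpha * p
            r = r - alpha * Ap
            res = np.linalg.norm(r) / max(rhs_norm, 1e-300)
            if res < tol:
                break
            z = precond * r
            rz_new = np.vdot(r, z).real
            p = z + (rz_new / rz) * p
            rz = rz_new
        self.last_info = _SolveInfo("cg", it, float(np.linalg.norm(r) / max(rhs_norm, 1e-300)))
        return x

    # -- dense materialisation (small systems / oracle) ------------------

    def materialize(self, n_echoes: int = 1) -> np.ndarray:
        """Dense matrix of S for one echo, (C * n_samples, N) over voxels.

        Only sensible for small grids; used for the SVD cache and as an
        exact reference in tests.
        """
        nz, ny, nx = self.coils.maps.shape[1:]
        n = nz * ny * nx
        if n > 8192:
            raise ValueError("grid too large to materialise densely")
        cols = []
        eye = np.eye(n)
        for j in range(n):
            img = eye[j].reshape(1, nz, ny, nx).astype(complex)
            ksp = self.apply(img)[:, 0]  # (C, z, y, x)
            cols.append(ksp.ravel())
        return np.stack(cols, axis=1)

    @property
    def svd(self):
        """Cached SVD (U, s, Vh) of the materialised single-echo operator."""
        if self._svd_cache is None:
            s_mat = self.materialize()
            u, s, vh = np.linalg.svd(s_mat, full_matrices=False)
            self._svd_cache = {"matrix": s_mat, "U": u, "s": s, "Vh": vh}
        return self._svd_cache

    def _solve_dense(self, rhs, lam2):
        cache = self.svd
        vh, s = cache["Vh"], cache["s"]
        nz, ny, nx = self.coils.maps.shape[1:]
        ne = rhs.shape[0]
        lam2_e = np.broadcast_to(lam2, (ne, 1, 1, 1)) if lam2.ndim else np.full(
            (ne, 1, 1, 1), float(lam2)
        )
        out = np.empty_like(rhs)
        for e in range(ne):
            l2 = float(lam2_e[e, 0, 0, 0])
            b = vh @ rhs[e].ravel()
            out[e] = (vh.conj().T @ (b / (1.0 + l2 * s**2))).reshape(nz, ny, nx)
        self.last_info = _SolveInfo("dense", 0, 0.0)
        return out


def estimate_coils_from_calibration(
    kspace: np.ndarray, mask: SamplingMask, calibration_lines: int | None = None
) -> CoilSet:
    """Autocalibrated coil sensitivities from the fully sampled centre block.

    A simple low-resolution estimate: inverse-transform the calibration
    region of the first echo and normalise by the RSS.  Plumbing for
    external data; simulations use the known maps.
    """
    calib = calibration_lines or mask.calibration_lines
    if calib <= 0:
        raise ValueError("no calibration region available")
    c, e, nz, ny, nx = kspace.shape
    lo = (ny - calib) // 2
    window = np.zeros((nz, ny, nx))
    window[:, lo : lo + calib, :] = np.hanning(calib)[None, :, None]
    low = ifftc(kspace[:, 0] * window[None])
    rss = np.sqrt(np.sum(np.abs(low) ** 2, axis=0))
    rss = np.where(rss > 1e-12 * rss.max(), rss, np.inf)
    return CoilSet(low / rss[None])
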