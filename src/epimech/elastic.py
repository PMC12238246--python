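"""Fourier-space Boussinesq kernel for an elastic half-space surface.

The displacement of the gel surface under a tangential traction field T is,
in Fourier space, ``u~(k) = G~(k) T~(k)`` with the 2x2 Green tensor

    G~(k) = 2 (1 + nu) / (E k^3) * [[(1-nu) k^2 + nu ky^2,  -nu kx ky],
                                    [-nu kx ky,  (1-nu) k^2 + nu kx^2]]

(thick-substrate limit).  Both the synthetic forward model and the FTTC
inversion evaluate this kernel on the same periodic grid, which makes the
pair exactly consistent: inversion of a forward-computed field at λ = 0
recovers the traction to rounding error.  Wrap-around is controlled by
keeping the traction pattern compact within the grid (a zero margin around
the pattern plays the role of padding); ``pad_factor > 1`` embeds the field
in a larger periodic box when an isolated, non-periodic scene is needed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["greens_tensor_fourier", "forward_displacement", "invert_traction"]


def _wavevectors(n: int, spacing: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = 2.0 * np.pi * np.fft.fftfreq(n, d=spacing)
    kx, ky = np.meshgrid(k, k)
    kmag = np.hypot(kx, ky)
    return kx, ky, kmag


def greens_tensor_fourier(n: int, spacing: float, E: float, nu: float
                          ) -> np.ndarray:
    """Green tensor on an n×n grid, shape (n, n, 2, 2), units µm/Pa.

    The k = 0 entry is set to zero: a balanced (zero net force) traction
    field produces no rigid surface translation, and the inverse problem is
    undefined at DC.
    """
    kx, ky, k = _wavevectors(n, spacing)
    k_safe = np.where(k == 0, 1.0, k)
    pref = 2.0 * (1.0 + nu) / (E * k_safe ** 3)
    G = np.empty((n, n, 2, 2))
    G[..., 0, 0] = pref * ((1.0 - nu) * k ** 2 + nu * ky ** 2)
    G[..., 1, 1] = pref * ((1.0 - nu) * k ** 2 + nu * kx ** 2)
    G[..., 0, 1] = G[..., 1, 0] = pref * (-nu * kx * ky)
    G[k == 0] = 0.0
    return G


def _pad_and_fft(tx: np.ndarray, ty: np.ndarray, pad_factor: int
                 ) -> tuple[np.ndarray, np.ndarray, int]:
    n = tx.shape[0]
    N = n * pad_factor
    px = np.zeros((N, N))
    py = np.zeros((N, N))
    px[:n, :n] = tx
    py[:n, :n] = ty
    return np.fft.fft2(px), np.fft.fft2(py), N


def forward_displacement(tx: np.ndarray, ty: np.ndarray, spacing: float,
                         E: float, nu: float, pad_factor: int = 1
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Surface displacement (µm) generated by a traction field (Pa).

    Parameters are the square (n, n) traction components, the grid spacing
    in µm, and the gel modulus/Poisson ratio.
    """
    if tx.shape != ty.shape or tx.shape[0] != tx.shape[1]:
        raise ValueError("traction components must be equal square arrays")
    Tx, Ty, N = _pad_and_fft(tx, ty, pad_factor)
    G = greens_tensor_fourier(N, spacing, E, nu)
    Ux = G[..., 0, 0] * Tx + G[..., 0, 1] * Ty
    Uy = G[..., 1, 0] * Tx + G[..., 1, 1] * Ty
    n = tx.shape[0]
    ux = np.real(np.fft.ifft2(Ux))[:n, :n]
    uy = np.real(np.fft.ifft2(Uy))[:n, :n]
    return ux, uy


def invert_traction(ux: np.ndarray, uy: np.ndarray, spacing: float,
                    E: float, nu: float, lam: float,
                    pad_factor: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Tikhonov-regularized FTTC inversion: displacement (µm) → traction (Pa).

    Solves ``min ||G T − u||² + λ² ||T||²`` per wavevector; ``lam`` has the
    units of the Green tensor (µm/Pa), so λ = 0 reproduces the unregularized
    inverse.  The DC component is forced to zero (net-force-free traction).
    """
    if lam < 0:
        raise ValueError("regularization parameter must be non-negative")
    if ux.shape != uy.shape or ux.shape[0] != ux.shape[1]:
        raise ValueError("displacement components must be equal square arrays")
    Ux, Uy, N = _pad_and_fft(ux, uy, pad_factor)
    G = greens_tensor_fourier(N, spacing, E, nu)
    # per-k 2x2 normal equations (G symmetric): (G·G + λ²I) T = G·u
    A00 = G[..., 0, 0] ** 2 + G[..., 0, 1] ** 2 + lam ** 2
    A11 = G[..., 1, 1] ** 2 + G[..., 0, 1] ** 2 + lam ** 2
    A01 = G[..., 0, 1] * (G[..., 0, 0] + G[..., 1, 1])
    b0 = G[..., 0, 0] * Ux + G[..., 0, 1] * Uy
    b1 = G[..., 0, 1] * Ux + G[..., 1, 1] * Uy
    det = A00 * A11 - A01 ** 2
    det = np.where(det == 0, 1.0, det)
    Tx = (A11 * b0 - A01 * b1) / det
    Ty = (A00 * b1 - A01 * b0) / det
    Tx[0, 0] = Ty[0, 0] = 0.0
    n = ux.shape[0]
    tx = np.real(np.fft.ifft2(Tx))[:n, :n]
    ty = np.real(np.fft.ifft2(Ty))[:n, :n]
    return tx, ty
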