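"""Batched small-matrix helpers shared by the generator, sampler and
postprocessing (stationary covariances and spectral radii for stacks of
person-level lag matrices)."""

from __future__ import annotations

import numpy as np

__all__ = ["batch_spectral_radius", "batch_stationary_cov", "psd_factor"]


def psd_factor(matrix: np.ndarray) -> np.ndarray:
    """Factor L with L L' = matrix for a symmetric PSD matrix, exact for
    singular inputs (eigendecomposition with clipped spectrum)."""
    w, v = np.linalg.eigh((matrix + matrix.T) / 2)
    return v * np.sqrt(np.clip(w, 0.0, None))


def batch_spectral_radius(phi: np.ndarray) -> np.ndarray:
    """Spectral radius of a (..., p, p) stack of lag matrices."""
    return np.max(np.abs(np.linalg.eigvals(phi)), axis=-1)


def batch_stationary_cov(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Stationary covariance for each (phi, diag psi) pair in a stack.

    Solves vec(Sigma) = (I - phi (x) phi)^{-1} vec(Psi) with a batched
    p^2 x p^2 solve; callers must ensure spectral radius < 1.

    Parameters
    ----------
    phi : (..., p, p)
    psi : (..., p) innovation variances (diagonal innovation covariance)
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    p = phi.shape[-1]
    # Kronecker product phi (x) phi for each batch element.
    kron = np.einsum("...ij,...kl->...ikjl", phi, phi).reshape(*phi.shape[:-2], p * p, p * p)
    eye = np.eye(p * p)
    vec_psi = np.zeros((*phi.shape[:-2], p * p))
    idx = np.arange(p)
    vec_psi[..., idx * p + idx] = psi
    vec_sigma = np.linalg.solve(eye - kron, vec_psi[..., None])[..., 0]
    sigma = vec_sigma.reshape(*phi.shape[:-2], p, p)
    return (sigma + np.swapaxes(sigma, -1, -2)) / 2
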