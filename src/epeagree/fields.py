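"""Stationary Gaussian random field synthesis on regular grids.

Fields are generated by circulant embedding: the target exponential
covariance is laid out on a torus twice the requested size, its FFT gives
the (non-negative, after clipping) spectral weights, and complex white
noise shaped by the square-root spectrum is transformed back.  The
doubled torus is cropped so that wrap-around correlation does not leak
into the returned window.  Marginals are standard normal; covariance is
exp(-d / range_km).
"""

from __future__ import annotations

import numpy as np

__all__ = ["exponential_gaussian_field"]


def _embedding_spectrum(
    n_rows: int, n_cols: int, dy: float, dx: float, range_km: float
) -> tuple[np.ndarray, int, int]:
    m, n = 2 * n_rows, 2 * n_cols
    iy = np.minimum(np.arange(m), m - np.arange(m)) * dy
    ix = np.minimum(np.arange(n), n - np.arange(n)) * dx
    d = np.hypot(iy[:, None], ix[None, :])
    cov = np.exp(-d / range_km)
    lam = np.fft.fft2(cov).real
    # exponential covariance is not exactly embeddable; tiny negative
    # eigenvalues are clipped, which perturbs the covariance negligibly
    lam = np.clip(lam, 0.0, None)
    return lam, m, n


def exponential_gaussian_field(
    n_fields: int,
    n_rows: int,
    n_cols: int,
    dx: float,
    range_km: float,
    rng: np.random.Generator,
    dy: float | None = None,
) -> np.ndarray:
    """Draw independent Gaussian fields with exponential spatial covariance.

    Parameters
    ----------
    n_fields : int
        Number of independent replicates (e.g. days).
    n_rows, n_cols : int
        Grid shape of the returned window.
    dx : float
        Cell size in km (dy defaults to dx).
    range_km : float
        e-folding correlation length of exp(-d / range_km).
    rng : numpy.random.Generator
        Source of randomness.

    Returns
    -------
    ndarray of shape (n_fields, n_rows, n_cols) with N(0, 1) marginals.
    """
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    dy = dx if dy is None else dy
    lam, m, n = _embedding_spectrum(n_rows, n_cols, dy, dx, range_km)
    root = np.sqrt(lam / (m * n))
    # real and imaginary parts of one transform are independent fields,
    # so half as many complex draws (and FFTs) cover n_fields
    half = (n_fields + 1) // 2
    eps = rng.standard_normal((half, m, n)) + 1j * rng.standard_normal((half, m, n))
    z = np.fft.fft2(root[None, :, :] * eps)
    out = np.concatenate([z.real, z.imag], axis=0)[:n_fields]
    return out[:, :n_rows, :n_cols]
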