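"""Centered FFT helpers and exact sub-pixel spectrum shifts.

Every spectrum in this package is DC-centered: the zero-frequency bin sits
at ``(n // 2, m // 2)``.  Frequencies are expressed in cycles per pixel
(x along columns, y along rows).  Spectrum shifts are always performed by
multiplying the spatial-domain signal with a complex phase ramp, which is
exact for non-integer shifts; frequency bins are never rolled.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c", "freq_grids", "radial_freq", "shift_spectrum"]


def fft2c(image: np.ndarray) -> np.ndarray:
    """2D FFT with the DC bin moved to the array center."""
    return np.fft.fftshift(np.fft.fft2(image))


def ifft2c(spectrum: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c` (returns a complex image)."""
    return np.fft.ifft2(np.fft.ifftshift(spectrum))


def freq_grids(shape: tuple[int, int],
               d: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Centered frequency grids (FX, FY) in cycles per pixel / d."""
    ny, nx = shape
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=d))
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=d))
    return np.meshgrid(fx, fy)


def radial_freq(shape: tuple[int, int], d: float = 1.0) -> np.ndarray:
    """Centered radial frequency magnitude in cycles per pixel / d."""
    fx, fy = freq_grids(shape, d=d)
    return np.hypot(fx, fy)


def shift_spectrum(spectrum: np.ndarray, k: tuple[float, float],
                   pixel_scale: float = 1.0) -> np.ndarray:
    """Evaluate a centered spectrum at ``k' + k``: new(k') = old(k' + k).

    Implemented as ``F[F^-1(S) * exp(-i 2 pi k . r)]`` so that arbitrary
    sub-bin shifts are exact.  ``k`` is in cycles per *original* pixel;
    ``pixel_scale`` is the grid's pixel size in original-pixel units (0.5
    on a 2x upsampled grid).
    """
    kx, ky = k
    if kx == 0.0 and ky == 0.0:
        return spectrum.copy()
    ny, nx = spectrum.shape
    x = np.arange(nx) * pixel_scale
    y = np.arange(ny) * pixel_scale
    X, Y = np.meshgrid(x, y)
    ramp = np.exp(-2j * np.pi * (kx * X + ky * Y))
    return fft2c(ifft2c(spectrum) * ramp)
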