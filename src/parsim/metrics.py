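"""Quantification utilities: SNR, FWHM resolution, and track statistics.

The SNR estimator follows the background-region convention used for raw
fluorescence frames: the noise statistics (mean and variance) come from a
manually designated structure-free region, the signal is the mean count
excess of a structure region over that background, and
``SNR_dB = 10 log10(Signal / MSE_noise)``.

Track statistics quantify tip motion of tubulating organelles: signed
frame-to-frame displacement projected onto a running motion axis, a
three-state direction label (forward / backward / static with a dead
band), instantaneous velocity, and the same velocity recomputed on a
temporally downsampled track to show what a slower camera would report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SnrReport",
    "Track",
    "TrackStats",
    "estimate_snr",
    "stack_snr",
    "measure_fwhm",
    "track_stats",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class SnrReport:
    mu_noise: float
    mse_noise: float
    mu_signal: float
    signal: float
    snr_db: float
    n_images: int = 1
    failures: list = field(default_factory=list)


@dataclass
class Track:
    """Time-ordered tip coordinates (pixels) with timestamps (ms)."""

    xy: np.ndarray  # (n, 2) columns (x, y) in pixels
    t_ms: np.ndarray
    pixel_size: float = 65.0  # nm

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be (n, 2)")
        if len(self.t_ms) != len(self.xy):
            raise ValueError("timestamps must match coordinates")
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass(frozen=True)
class TrackStats:
    displacement_px: np.ndarray  # signed, per step
    direction: list  # "forward" | "backward" | "static"
    velocity_um_s: np.ndarray  # V at native sampling
    downsampled_velocity_um_s: np.ndarray  # V' at step-coarsened sampling
    step: int


def _region_pixels(image: np.ndarray, region) -> np.ndarray:
    """Accept a boolean mask or a (r0, r1, c0, c1) half-open rectangle."""
    region_arr = np.asarray(region)
    if region_arr.dtype == bool:
        return image[region_arr]
    r0, r1, c0, c1 = (int(v) for v in region)
    return image[r0:r1, c0:c1].ravel()


def estimate_snr(image: np.ndarray, noise_region, signal_region) -> SnrReport:
    """SNR of a single raw image from designated noise and signal regions.

    ``mu_noise`` and ``MSE_noise`` are the mean and variance over the
    noise (background-only) region; ``Signal = mu_signal - mu_noise``;
    ``SNR = 10 log10(Signal / MSE_noise)`` in dB.  Raises on a constant
    noise region or non-positive signal.
    """
    noise = _region_pixels(image, noise_region).astype(float)
    sig = _region_pixels(image, signal_region).astype(float)
    if noise.size == 0 or sig.size == 0:
        raise ValueError("noise and signal regions must be non-empty")
    mu_noise = float(noise.mean())
    mse_noise = float(((noise - mu_noise) ** 2).mean())
    mu_signal = float(sig.mean())
    signal = mu_signal - mu_noise
    if mse_noise == 0.0:
        raise ValueError("constant noise region: MSE_noise = 0")
    if signal <= 0.0:
        raise ValueError(
            f"signal not above background (mu_signal = {mu_signal:.3f}, "
            f"mu_noise = {mu_noise:.3f}); SNR undefined")
    snr_db = 10.0 * math.log10(signal / mse_noise)
    return SnrReport(mu_noise, mse_noise, mu_signal, signal, snr_db)


def stack_snr(stack: Sequence[np.ndarray], noise_region,
              signal_region) -> SnrReport:
    """Stack SNR: per-image SNRs averaged (signal and MSE also averaged).

    Images whose per-image estimate fails are listed in ``failures`` and
    excluded from the averages.
    """
    reports, failures = [], []
    for i, img in enumerate(stack):
        try:
            reports.append(estimate_snr(img, noise_region, signal_region))
        except ValueError as exc:
            failures.append((i, str(exc)))
    if not reports:
        raise ValueError(f"all {len(list(stack))} images failed: {failures}")
    return SnrReport(
        mu_noise=float(np.mean([r.mu_noise for r in reports])),
        mse_noise=float(np.mean([r.mse_noise for r in reports])),
        mu_signal=float(np.mean([r.mu_signal for r in reports])),
        signal=float(np.mean([r.signal for r in reports])),
        snr_db=float(np.mean([r.snr_db for r in reports])),
        n_images=len(reports),
        failures=failures,
    )


def _gauss(x, amp, mu, sigma, offset):
    return offset + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def measure_fwhm(image: np.ndarray, point: tuple[float, float],
                 axis: str = "x", window: int = 15,
                 pixel_size: float = 65.0) -> float:
    """FWHM (nm) of a point feature from a 1-D Gaussian profile fit.

    Extracts a line profile of half-width ``window`` through ``point``
    (given as (x, y) in pixels) along ``axis``, fits amplitude/center/
    sigma/offset, and returns ``2 sqrt(2 ln 2) sigma x pixel_size``.
    """
    x0, y0 = int(round(point[0])), int(round(point[1]))
    ny, nx = image.shape
    if axis == "x":
        lo, hi = max(x0 - window, 0), min(x0 + window + 1, nx)
        profile = image[y0, lo:hi]
        coords = np.arange(lo, hi, dtype=float)
        center = float(point[0])
    elif axis == "y":
        lo, hi = max(y0 - window, 0), min(y0 + window + 1, ny)
        profile = image[lo:hi, x0]
        coords = np.arange(lo, hi, dtype=float)
        center = float(point[1])
    else:
        raise ValueError("axis must be 'x' or 'y'")
    if np.ptp(profile) == 0:
        raise ValueError("flat profile: cannot fit a peak")
    amp0 = float(profile.max() - profile.min())
    try:
        popt, _ = curve_fit(
            _gauss, coords, profile,
            p0=[amp0, center, 2.0, float(profile.min())],
            maxfev=5000)
    except RuntimeError as exc:
        raise ValueError(f"Gaussian fit failed: {exc}") from exc
    sigma = abs(popt[2])
    return GAUSSIAN_FWHM_FACTOR * sigma * pixel_size


def _running_axes(xy: np.ndarray, window: int = 10) -> np.ndarray:
    """Unit motion axis per step: PCA major axis of a trailing window,
    oriented along the net displacement so 'forward' means extension."""
    n = len(xy)
    axes = np.zeros((n - 1, 2))
    for i in range(n - 1):
        lo = max(0, i + 2 - window)
        pts = xy[lo:i + 2]
        centered = pts - pts.mean(axis=0)
        if len(pts) >= 2 and np.any(centered):
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            axis = vt[0]
        else:
            axis = np.array([1.0, 0.0])
        net = xy[i + 1] - xy[lo]
        if np.dot(axis, net) < 0:
            axis = -axis
        axes[i] = axis
    return axes


def track_stats(track: Track, step: int = 25,
                static_deadband_px: float = 0.5,
                axis_window: int = 10) -> TrackStats:
    """Displacement, direction labels and velocities of a tip track.

    Displacement per step is the signed projection of the frame-to-frame
    motion onto the running tubulation axis (PCA major axis of a trailing
    ``axis_window``-point window).  Direction is labeled static when the
    magnitude is below ``static_deadband_px``.  ``V`` is displacement over
    the native sampling interval in um/s; ``V'`` repeats the computation
    on the track subsampled by ``step`` (e.g. 25 maps a 7.35 ms cadence to
    183.75 ms).  ``step=1`` returns V' identical to V.
    """
    if len(track) < 2:
        raise ValueError("a track needs at least two points")
    if step < 1:
        raise ValueError("step must be >= 1")

    def _velocities(xy: np.ndarray, t_ms: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
        axes = _running_axes(xy, axis_window)
        deltas = np.diff(xy, axis=0)
        disp = np.einsum("ij,ij->i", deltas, axes)  # px, signed
        dt_s = np.diff(t_ms) / 1000.0
        vel = disp * track.pixel_size / 1000.0 / dt_s  # um/s
        return disp, vel

    disp, vel = _velocities(track.xy, track.t_ms)
    labels = ["static" if abs(d) < static_deadband_px
              else ("forward" if d > 0 else "backward") for d in disp]

    idx = np.arange(0, len(track), step)
    if len(idx) >= 2:
        _, vel_ds = _velocities(track.xy[idx], track.t_ms[idx])
    else:
        vel_ds = np.array([])
    return TrackStats(displacement_px=disp, direction=labels,
                      velocity_um_s=vel,
                      downsampled_velocity_um_s=vel_ds, step=step)
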