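"""Super-resolved image assembly: shift, fuse, synthesize, deconvolve.

The separated spectral orders are moved to their true positions on a 2x
upsampled frequency grid, combined by a two-step spectral optimization --
a generalized Wiener weighting of all orders followed by an ideal
apodization to the extended cutoff -- and the same weighting applied to
the OTFs yields the synthesized SIM OTF whose inverse transform is the
deconvolution kernel for the final Richardson-Lucy pass.  A rolling
(sliding-window) driver multiplies the output frame rate by reusing the
most recent full pattern set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .fourier import fft2c, freq_grids, ifft2c
from .params import (EstimationError, IlluminationEstimate,
                     SpectralComponents, estimate_illumination,
                     separate_orders)
from .prep import SubROIStack, preprocess_stack, rl_deconvolve
from .simulate import OpticsModel, PatternSet, make_otf, make_psf, otf_at
from . import fourier

__all__ = [
    "FusionFilters",
    "ReconConfig",
    "ReconResult",
    "upsample_spectrum",
    "shift_order",
    "fuse_spectra",
    "synthesize_psf",
    "final_deconvolve",
    "reconstruct",
    "rolling_reconstruct",
]


class FusionFilters(BaseModel):
    """Tunables of the two-step spectral fusion."""

    wiener_parameter: float = Field(0.05, gt=0)
    notch_sigma_bins: float = Field(1.5, gt=0)  # upsampled-grid bins
    notch_depth: float = Field(1.0, ge=0, le=1.0)
    apodization: str = "triangle"  # W2 taper to the extended cutoff


class ReconConfig(BaseModel):
    """End-to-end reconstruction parameters."""

    optics: OpticsModel = OpticsModel()
    patterns: PatternSet = PatternSet()
    filters: FusionFilters = FusionFilters()
    border_width: int = 16
    border_sigma: float = 8.0
    #: the RL prefilter is multiplicative and distorts the linear 3-phase
    #: mixing model on small fields; parameter estimation and fusion run
    #: on the linear (background-subtracted, apodized) images by default
    pre_rl_iterations: int = 0
    final_rl_iterations: int = 10
    sector_halfwidth_deg: float = 2.5
    search_ring: tuple[float, float] = (0.5, 1.1)
    upsample: int = 2  # fixed linear-SIM upsampling
    reestimate_k_per_window: bool = False


@dataclass
class ReconResult:
    """Super-resolved image plus everything used to build it."""

    sr_image: np.ndarray
    fused_spectrum: np.ndarray
    synthesized_otf: np.ndarray
    synthesized_psf: np.ndarray
    estimates: list[IlluminationEstimate]
    qc: dict = field(default_factory=dict)


def upsample_spectrum(spectrum: np.ndarray, factor: int = 2) -> np.ndarray:
    """Zero-pad a centered spectrum onto a ``factor``-times-finer grid.

    Scaled by ``factor**2`` so spatial intensities are preserved under the
    inverse transform.  For even-sized inputs the (conjugate-unpaired)
    Nyquist row and column are dropped: embedded in a larger grid they
    would break Hermitian symmetry, and the optical passband ends well
    below them anyway.
    """
    ny, nx = spectrum.shape
    out = np.zeros((factor * ny, factor * nx), dtype=complex)
    oy, ox = (factor * ny - ny) // 2, (factor * nx - nx) // 2
    out[oy:oy + ny, ox:ox + nx] = spectrum
    if factor > 1:
        if ny % 2 == 0:
            out[oy, :] = 0
        if nx % 2 == 0:
            out[:, ox] = 0
    return out * factor ** 2


def shift_order(spectrum: np.ndarray, k: tuple[float, float],
                pixel_scale: float = 0.5) -> np.ndarray:
    """Move an order by ``k`` cycles/original-pixel on the upsampled grid.

    Spatial phase-ramp shift (exact for sub-bin ``k``); Parseval energy is
    conserved to rounding.  ``pixel_scale`` is the grid pixel size in
    original-pixel units (0.5 on the standard 2x grid).
    """
    ny, nx = spectrum.shape
    if abs(k[0]) * pixel_scale >= 0.5 or abs(k[1]) * pixel_scale >= 0.5:
        raise ValueError(f"shift {k} cycles/px beyond the representable "
                         f"range of the grid")
    return fourier.shift_spectrum(spectrum, k, pixel_scale=pixel_scale)


def _extended_cutoff(kc: float,
                     estimates: Sequence[IlluminationEstimate]) -> float:
    return kc + max(e.k_vector.magnitude for e in estimates)


def fuse_spectra(components: Sequence[SpectralComponents],
                 estimates: Sequence[IlluminationEstimate],
                 optics: OpticsModel, filters: FusionFilters,
                 upsample: int = 2,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Two-step spectral fusion of all separated orders.

    Step 1 -- generalized Wiener combination over every order d of every
    angle: ``sum_d m_d OTF_d*(k) C_d(k) / (sum_d m_d^2 |OTF_d(k)|^2 + w^2)``
    where ``C_d`` is the order shifted to its true position and normalized
    to unit modulation, and ``OTF_d`` is the analytically shifted OTF.
    Residual zero-order peaks at ``+-k_theta`` are suppressed by Gaussian
    notches.  Step 2 -- multiplication by an ideal apodization ``W2``
    (distance taper to the extended cutoff ``k_c + max|k_theta|``).

    Returns ``(fused_spectrum, synthesized_otf)`` on the upsampled grid;
    the synthesized OTF is the same combination applied to the OTFs
    themselves, apodized, and normalized to 1 at DC.
    """
    if len(components) != len(estimates) or not components:
        raise ValueError("need one estimate per component set")
    kc = optics.cutoff_cycles_per_px
    shape0 = components[0].center.shape
    up_shape = (upsample * shape0[0], upsample * shape0[1])
    pixel_scale = 1.0 / upsample
    fx, fy = freq_grids(up_shape, d=pixel_scale)
    rad = np.hypot(fx, fy)
    otf0 = otf_at(rad, kc)
    w2sq = filters.wiener_parameter ** 2

    num = np.zeros(up_shape, dtype=complex)
    den = np.full(up_shape, w2sq)
    otf_num = np.zeros(up_shape)
    notch_centers: list[tuple[float, float]] = []

    for comps, est in zip(components, estimates):
        k = est.k_vector.as_tuple()
        m = est.modulation
        phase = est.global_phase
        # order: (component, shift toward DC, unmixing gain, OTF offset)
        orders = [
            (comps.center, (0.0, 0.0), 1.0 + 0.0j, (0.0, 0.0)),
            (comps.low, (k[0], k[1]),
             np.exp(-1j * phase) / m, (k[0], k[1])),
            (comps.high, (-k[0], -k[1]),
             np.exp(1j * phase) / m, (-k[0], -k[1])),
        ]
        weights = [1.0, m, m]
        for (comp, shift, gain, off), wd in zip(orders, weights):
            if not np.any(comp):
                continue  # absent order (e.g. widefield-only input)
            comp_up = upsample_spectrum(comp, upsample)
            if shift != (0.0, 0.0):
                comp_up = shift_order(comp_up, shift, pixel_scale)
            comp_up = comp_up * gain
            otf_d = otf_at(np.hypot(fx + off[0], fy + off[1]), kc)
            num += wd * otf_d * comp_up
            den += wd ** 2 * otf_d ** 2
            otf_num += wd * otf_d ** 2
        notch_centers.extend([(k[0], k[1]), (-k[0], -k[1])])

    fused = num / den
    otf_syn = otf_num / den

    if filters.notch_depth > 0:
        bin_size = 1.0 / (up_shape[1] * pixel_scale)  # cycles/px per bin
        sig = filters.notch_sigma_bins * bin_size
        for cx, cy in notch_centers:
            d2 = (fx - cx) ** 2 + (fy - cy) ** 2
            fused *= 1.0 - filters.notch_depth * np.exp(-d2 / (2 * sig ** 2))

    k_ext = _extended_cutoff(kc, estimates)
    w2 = np.clip(1.0 - rad / k_ext, 0.0, None)
    fused *= w2
    otf_syn *= w2
    dc = otf_syn[up_shape[0] // 2, up_shape[1] // 2]
    if dc > 0:
        otf_syn = otf_syn / dc
    return fused, otf_syn


def synthesize_psf(synthesized_otf: np.ndarray,
                   support: Optional[int] = None) -> np.ndarray:
    """Real-space SIM deconvolution kernel from the synthesized OTF.

    Inverse transform, recentered at (n//2, m//2), truncated to a compact
    ``support x support`` window (default: a quarter of the grid) and
    renormalized to sum 1.  The sidelobes created by the multi-lobed
    synthesized passband are retained -- they are what the final
    deconvolution is meant to remove from the image.
    """
    ny, nx = synthesized_otf.shape
    psf = np.fft.fftshift(ifft2c(synthesized_otf)).real
    psf = np.clip(psf, 0.0, None)
    if support is None:
        support = max(17, min(ny, nx) // 4) | 1
    cy, cx = ny // 2, nx // 2
    h = support // 2
    psf = psf[cy - h:cy + h + 1, cx - h:cx + h + 1]
    s = psf.sum()
    if s <= 0:
        raise ValueError("degenerate synthesized OTF: empty PSF")
    return psf / s


def final_deconvolve(sr_image: np.ndarray, sim_psf: np.ndarray,
                     iterations: int = 10) -> np.ndarray:
    """Richardson-Lucy with the synthesized SIM PSF (sidelobe cleanup)."""
    return rl_deconvolve(np.clip(sr_image, 0.0, None), sim_psf, iterations)


def _group_by_angle(stack: SubROIStack, n_angles: int
                    ) -> list[list[np.ndarray]]:
    groups: list[list[Optional[np.ndarray]]] = [[None] * 3
                                                for _ in range(n_angles)]
    for img, (a, p) in zip(stack.images, stack.pattern_labels):
        if not (0 <= a < n_angles and 0 <= p < 3):
            raise ValueError(f"label (angle={a}, phase={p}) outside the "
                             f"{n_angles}-angle, 3-phase pattern set")
        groups[a][p] = img
    for a, g in enumerate(groups):
        if any(x is None for x in g):
            raise ValueError(
                f"incomplete pattern set: angle {a} is missing phases "
                f"{[p for p, x in enumerate(g) if x is None]}")
    return groups  # type: ignore[return-value]


def reconstruct(stack: SubROIStack, config: ReconConfig,
                estimates: Optional[list[IlluminationEstimate]] = None,
                ) -> ReconResult:
    """Full pipeline: prep -> estimate -> separate -> shift -> fuse ->
    synthesize -> deconvolve.

    ``estimates`` may carry k-vectors from an earlier window; phases are
    still refreshed per call unless the estimates are used verbatim (see
    :func:`rolling_reconstruct`).  Deterministic given config and input.
    """
    pat = config.patterns
    expected = pat.n_angles * 3
    if len(stack) != expected:
        raise ValueError(f"incomplete pattern set: expected {expected} "
                         f"images, got {len(stack)}")
    shape = stack.images[0].shape
    otf = make_otf(config.optics, shape)
    psf = make_psf(config.optics, shape)
    kc = config.optics.cutoff_cycles_per_px

    pre = preprocess_stack(stack, psf=psf,
                           border_width=config.border_width,
                           border_sigma=config.border_sigma,
                           rl_iterations=config.pre_rl_iterations)
    groups = _group_by_angle(pre, pat.n_angles)

    ests: list[IlluminationEstimate] = []
    comps_all: list[SpectralComponents] = []
    for a, images in enumerate(groups):
        try:
            if estimates is not None:
                est, comps = _reuse_k_estimate(images, kc, estimates[a])
            else:
                est, comps = estimate_illumination(
                    images, otf, kc, prior_angle_deg=pat.angles[a],
                    sector_halfwidth_deg=config.sector_halfwidth_deg,
                    ring=config.search_ring)
        except EstimationError as exc:
            raise EstimationError(
                f"[stage: params, angle {a}] {exc}") from exc
        ests.append(est)
        comps_all.append(comps)

    fused, otf_syn = fuse_spectra(comps_all, ests, config.optics,
                                  config.filters, config.upsample)
    sr_complex = ifft2c(fused)
    max_re = float(np.abs(sr_complex.real).max())
    max_im = float(np.abs(sr_complex.imag).max())
    sr = sr_complex.real
    sim_psf = synthesize_psf(otf_syn)
    final = final_deconvolve(sr, sim_psf, config.final_rl_iterations)

    qc = {
        "max_imag_ratio": max_im / max_re if max_re > 0 else 0.0,
        "extended_cutoff": _extended_cutoff(kc, ests),
        "modulations": [e.modulation for e in ests],
        "flagged_low_modulation": any(e.modulation < 0.15 for e in ests),
        "k_subpixel": all(e.k_vector.precision == "subpixel" for e in ests),
    }
    return ReconResult(sr_image=final, fused_spectrum=fused,
                       synthesized_otf=otf_syn, synthesized_psf=sim_psf,
                       estimates=ests, qc=qc)


def _reuse_k_estimate(images, kc, prior: IlluminationEstimate):
    """Refresh phases and modulation for a window while starting the
    k-vector refinement from an earlier window's estimate (vibration
    perturbs the fringe phase far more than its period)."""
    from .params import (estimate_modulation_phase,
                         lockin_phase_differences, refine_k_subpixel)
    spectra = [fft2c(img) for img in images]
    phi1, phi2 = lockin_phase_differences(spectra,
                                          prior.k_vector.as_tuple())
    comps = separate_orders(spectra, (0.0, phi1, phi2), m=1.0)
    kv = refine_k_subpixel(comps, kc, prior.k_vector)
    m, global_phase = estimate_modulation_phase(comps, kc, kv.as_tuple())
    comps.k_vector = kv
    comps.modulation = m
    est = IlluminationEstimate(
        k_vector=kv, phase_differences=(phi1, phi2),
        global_phase=global_phase, modulation=m,
        objective_trace={"reused_k": prior.k_vector.as_tuple()})
    return est, comps


def rolling_reconstruct(images: Sequence[np.ndarray], config: ReconConfig,
                        step: int) -> list[ReconResult]:
    """Sliding-window reconstruction over a time series of sub-images.

    ``images`` are in acquisition order, cycling through the pattern set
    (image ``i`` carries pattern ``i mod set_size``).  The window of one
    full set advances by ``step`` sub-images; each window keeps the newest
    image of every (angle, phase).  Output count is
    ``floor((n_total - set_size) / step) + 1``.  The first window's
    k-vectors are reused for later windows (phases are refreshed per
    window) unless ``config.reestimate_k_per_window`` is set.
    """
    set_size = config.patterns.n_angles * 3
    if set_size % step != 0:
        raise ValueError(f"rolling step {step} does not divide the "
                         f"pattern-set size {set_size}")
    n = len(images)
    if n < set_size:
        raise ValueError(f"need at least {set_size} images, got {n}")
    n_out = (n - set_size) // step + 1
    results: list[ReconResult] = []
    first_estimates: Optional[list[IlluminationEstimate]] = None
    for w in range(n_out):
        o = w * step
        window = images[o:o + set_size]
        labels = [((o + j) % set_size // 3, (o + j) % set_size % 3)
                  for j in range(set_size)]
        stack = SubROIStack(list(window), labels,
                            provenance=list(range(o, o + set_size)))
        reuse = None
        if w > 0 and not config.reestimate_k_per_window:
            reuse = first_estimates
        res = reconstruct(stack, config, estimates=reuse)
        if w == 0:
            first_estimates = res.estimates
        results.append(res)
    return results
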