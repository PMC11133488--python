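"""Illumination-parameter estimation from low-SNR raw spectra.

The estimation chain that makes reconstruction possible at raw SNRs around
or below 0 dB:

1. *Phase step first.*  The pairwise differences of the three per-phase
   spectra cancel the zero order (and any constant background) exactly,
   leaving pure +-1-order mixtures.  Because the two first-order
   components of an incoherent sample are close to statistically
   independent, the magnitude of their weighted cross-correlation is
   minimized when the assumed phase step matches the truth; a
   deterministic grid plus golden-section search over the common step
   recovers it without the fringe peak being visible.
2. *Prior-constrained coarse peak search.*  The fringe k-vector loaded on
   the SLM is known up to small drifts, so the separated first-order peak
   is searched only inside a ring of 0.5-1.1 x the OTF cutoff intersected
   with a +-2.5 degree sector around the nominal fringe direction.
3. *Sub-pixel k refinement.*  The k-vector is polished by maximizing the
   complex overlap between the zero-order and the phase-ramp-shifted
   first-order spectra.  Both factors carry the same symmetrized OTF
   weighting, which turns the overlap into a true weighted
   autocorrelation of the sample spectrum -- maximized at zero lag by
   Cauchy-Schwarz, so the refinement is unbiased even for scenes with a
   dominant low-frequency peak.
4. *Per-image phases by matched lock-in.*  With k known, each raw
   spectrum is shifted by +k and correlated against the widefield
   spectrum over a small low-frequency disc.  The zero-order contribution
   is identical for every phase image and drops out of pairwise
   differences, leaving ``c_i = K0 + A e^{i phi_i}``; the two phase
   differences follow in closed form from the complex ratio
   ``(c_2 - c_1) / (c_3 - c_1)``.
5. *Modulation and global phase.*  After re-separation with the refined
   phases, a weighted regression of the shifted low order against the
   zero order yields ``m e^{i phi_1}`` directly.

Convention: a fringe ``1 + m cos(2 pi k.r + phi)`` contributes
``(m/2) e^{+i phi}`` to the low order ``S(k - k_theta)`` and the
conjugate to the high order, so the mixing matrix rows are
``[1, (m/2) e^{+i phi_i}, (m/2) e^{-i phi_i}]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .fourier import fft2c, freq_grids, ifft2c
from .simulate import otf_at

__all__ = [
    "EstimationError",
    "KVector",
    "IlluminationEstimate",
    "SpectralComponents",
    "mixing_matrix",
    "difference_matrix",
    "difference_spectra",
    "build_weight",
    "estimate_phase_step",
    "estimate_phase_differences",
    "lockin_phase_differences",
    "separate_orders",
    "coarse_k_search",
    "refine_k_subpixel",
    "estimate_modulation_phase",
    "estimate_illumination",
    "baseline_estimate",
]

PHASE_SEARCH_RANGE = (np.pi / 3, np.pi)
CONDITION_LIMIT = 1e6


class EstimationError(RuntimeError):
    """Raised when an illumination parameter cannot be estimated."""


@dataclass
class KVector:
    """Illumination fringe k-vector in cycles per pixel."""

    kx: float
    ky: float
    precision: str = "pixel"  # "pixel" | "subpixel"
    peak_value: float = 0.0
    on_boundary: bool = False

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.kx, self.ky))

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.ky, self.kx)))

    def as_tuple(self) -> tuple[float, float]:
        return (self.kx, self.ky)


@dataclass
class IlluminationEstimate:
    """Everything estimated for one illumination angle."""

    k_vector: KVector
    phase_differences: tuple[float, float]  # (phi2-phi1, phi3-phi1), rad
    global_phase: float  # phi_1 re-anchored after refinement, rad
    modulation: float
    objective_trace: dict = field(default_factory=dict)
    condition_number: float = 0.0
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "k": [self.k_vector.kx, self.k_vector.ky],
            "k_precision": self.k_vector.precision,
            "phase_differences": list(self.phase_differences),
            "global_phase": self.global_phase,
            "modulation": self.modulation,
            "condition_number": self.condition_number,
            "converged": self.converged,
        }


@dataclass
class SpectralComponents:
    """Separated 0 / low / high order spectra for one angle (unshifted).

    ``low`` carries ``S(k - k_theta) H(k)`` (its sample-DC peak sits at
    ``+k_theta``), ``high`` the conjugate order peaking at ``-k_theta``.
    """

    center: np.ndarray
    low: np.ndarray
    high: np.ndarray
    k_vector: Optional[KVector] = None
    phases: Optional[tuple[float, float, float]] = None
    modulation: float = 1.0


def mixing_matrix(phases: Sequence[float], m: float,
                  amplitude: float = 1.0) -> np.ndarray:
    """3x3 phase-mixing matrix (including the I0/2 prefactor)."""
    rows = [[1.0, (m / 2.0) * np.exp(1j * p), (m / 2.0) * np.exp(-1j * p)]
            for p in phases]
    return (amplitude / 2.0) * np.array(rows)


def difference_matrix(phi1: float, phi2: float) -> np.ndarray:
    """2x2 mixing matrix of the two difference spectra (phase-diff form,
    first phase taken as 0)."""
    return np.array([
        [np.exp(1j * phi1) - 1.0, np.exp(-1j * phi1) - 1.0],
        [np.exp(1j * phi2) - 1.0, np.exp(-1j * phi2) - 1.0],
    ])


def difference_spectra(spectra: Sequence[np.ndarray]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(D2 - D1, D3 - D1): zero-order-free mixtures of the +-1 orders.

    Any component common to the three phase images -- the zero order, a
    constant background, fixed-pattern structure -- cancels identically.
    """
    d1, d2, d3 = spectra
    if d1.shape != d2.shape or d1.shape != d3.shape:
        raise ValueError("phase spectra must share one shape")
    return d2 - d1, d3 - d1


def build_weight(otf: np.ndarray, kc: float, shape_radial: np.ndarray,
                 ring: tuple[float, float] = (0.3, 1.0)) -> np.ndarray:
    """Cross-correlation weight w(k): ring indicator x OTF^2.

    Vanishes at DC (killing residual zero-order contributions) and
    emphasizes the well-transferred mid frequencies where the two
    first-order components actually overlap.
    """
    mask = (shape_radial >= ring[0] * kc) & (shape_radial <= ring[1] * kc)
    return mask.astype(float) * otf ** 2


def _solve_diff(e1: np.ndarray, e2: np.ndarray, phi1: float, phi2: float
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Invert the 2x2 difference mixing for candidate phase differences."""
    mp = difference_matrix(phi1, phi2)
    det = mp[0, 0] * mp[1, 1] - mp[0, 1] * mp[1, 0]
    if abs(det) < 1e-12:
        raise EstimationError(
            f"difference mixing matrix singular for phase differences "
            f"({phi1:.3f}, {phi2:.3f})")
    inv = np.array([[mp[1, 1], -mp[0, 1]], [-mp[1, 0], mp[0, 0]]]) / det
    low = inv[0, 0] * e1 + inv[0, 1] * e2
    high = inv[1, 0] * e1 + inv[1, 1] * e2
    cond = float(np.linalg.cond(mp))
    return low, high, cond


def _correlation_objective(e1, e2, w, phi1, phi2) -> float:
    """Normalized cross-correlation magnitude of the two separated
    first-order components (lower = more independent)."""
    low, high, _ = _solve_diff(e1, e2, phi1, phi2)
    num = abs(np.sum(w * low * np.conj(high)))
    den = np.sqrt(np.sum(w * np.abs(low) ** 2)
                  * np.sum(w * np.abs(high) ** 2))
    if den == 0:
        raise EstimationError("no modulation detected: zero first-order "
                              "energy in the difference spectra")
    return float(num / den)


def _golden_section(f, a, b, tol=1e-4, max_iter=60):
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def estimate_phase_step(spectra: Sequence[np.ndarray], weight: np.ndarray,
                        search: tuple[float, float] = PHASE_SEARCH_RANGE,
                        grid_points: int = 64) -> tuple[float, dict]:
    """Common phase step by 1-D cross-correlation minimization.

    Assumes the ladder ``(phi1, phi2) = (phi, 2 phi)`` and minimizes the
    weighted correlation of the two first orders separated from the
    difference spectra over ``phi`` in ``search`` -- a deterministic
    ``grid_points`` grid followed by golden-section refinement.
    """
    e1, e2 = difference_spectra(spectra)

    def step_obj(phi: float) -> float:
        return _correlation_objective(e1, e2, weight, phi, 2.0 * phi)

    lo, hi = search
    eps = 1e-3
    grid = np.linspace(lo + eps, hi - eps, grid_points)
    values = np.array([step_obj(p) for p in grid])
    if np.ptp(values) < 1e-12:
        raise EstimationError("no modulation detected: flat phase objective")
    i = int(np.argmin(values))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_points - 1)]
    phi_step = _golden_section(step_obj, a, b)
    trace = {"grid": grid.tolist(), "objective": values.tolist(),
             "phi_step": float(phi_step),
             "objective_at_step": float(step_obj(phi_step))}
    return float(phi_step), trace


def estimate_phase_differences(
        spectra: Sequence[np.ndarray], weight: np.ndarray,
        search: tuple[float, float] = PHASE_SEARCH_RANGE,
        grid_points: int = 64,
        ) -> tuple[tuple[float, float], dict]:
    """Initial phase differences from the 1-D step search.

    Returns ``((phi2 - phi1, phi3 - phi1), trace)`` on the exact 1:2
    ladder.  Per-image deviations from the ladder (registration jitter)
    are recovered later by :func:`lockin_phase_differences` once the
    fringe k-vector is known -- the pure cross-correlation objective
    cannot separate them from the scene's intrinsic order correlation.
    """
    phi_step, trace = estimate_phase_step(spectra, weight, search,
                                          grid_points)
    return (phi_step, 2.0 * phi_step), trace


def lockin_phase_differences(spectra: Sequence[np.ndarray],
                             k: tuple[float, float],
                             disc_radius_bins: float = 12.0,
                             ) -> tuple[float, float]:
    """Closed-form phase differences by matched lock-in at the fringe k.

    Each spectrum is shifted by ``+k`` (bringing the low order's sample-DC
    peak onto the origin) and correlated against the widefield (phase
    average) spectrum over a disc of ``disc_radius_bins`` frequency bins:
    ``c_i = K0 + A e^{i phi_i}`` with the zero-order term ``K0`` and gain
    ``A`` common to the three images.  The differences follow from
    ``R = (c2 - c1)/(c3 - c1) = (e^{i p1} - 1)/(e^{i p2} - 1)``, solved
    exactly: with ``a = arg R``, ``tan(p2/2) = sin a / (|R| - cos a)`` and
    ``p1 = p2 + 2 a``.
    """
    shape = spectra[0].shape
    ny, nx = shape
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny))
    ramp = np.exp(-2j * np.pi * (k[0] * X + k[1] * Y))
    fx, fy = freq_grids(shape)
    disc = np.hypot(fx, fy) < disc_radius_bins / max(ny, nx)
    wf = sum(spectra) / len(spectra)
    c = [np.sum(np.conj(wf[disc]) * fft2c(ifft2c(S) * ramp)[disc])
         for S in spectra]
    d21, d31 = c[1] - c[0], c[2] - c[0]
    if abs(d31) == 0:
        raise EstimationError("degenerate lock-in: identical phase images")
    R = d21 / d31
    a = float(np.angle(R))
    v = float(np.arctan2(np.sin(a), abs(R) - np.cos(a)))
    if v <= 0:
        v += np.pi
    u = v + a
    return float((2 * u) % (2 * np.pi)), float((2 * v) % (2 * np.pi))


def separate_orders(spectra: Sequence[np.ndarray],
                    phases: Sequence[float], m: float,
                    amplitude: float = 1.0) -> SpectralComponents:
    """Per-frequency inversion of the 3-phase mixing matrix.

    ``phases`` are the three absolute fringe phases (convention: the first
    is 0 before global-phase refinement).  Exact linear inversion -- no
    regularization; a condition number above 1e6 is refused.
    """
    d1, d2, d3 = spectra
    if m <= 0:
        raise EstimationError("modulation m must be positive to separate")
    mat = mixing_matrix(phases, m, amplitude)
    cond = float(np.linalg.cond(mat))
    if cond > CONDITION_LIMIT:
        raise EstimationError(
            f"mixing matrix ill-conditioned (cond = {cond:.3g}): phases "
            f"{tuple(float(p) for p in phases)} are too close modulo 2 pi")
    inv = np.linalg.inv(mat)
    stack = np.stack([d1, d2, d3])
    comps = np.tensordot(inv, stack, axes=(1, 0))
    return SpectralComponents(center=comps[0], low=comps[1], high=comps[2],
                              phases=tuple(float(p) for p in phases),
                              modulation=m)


def coarse_k_search(spectrum: np.ndarray, kc: float,
                    prior_angle_deg: Optional[float],
                    sector_halfwidth_deg: float = 2.5,
                    ring: tuple[float, float] = (0.5, 1.1),
                    ) -> KVector:
    """Pixel-precision fringe peak inside the prior ring-sector mask.

    The separated low-order spectrum peaks at ``+k_theta``; the search is
    restricted to radii ``ring x k_c`` (excluding residual zero-order
    power near DC) and, when a prior angle is given, to
    ``prior +- sector_halfwidth`` degrees around the fringe direction
    loaded on the SLM.
    """
    fx, fy = freq_grids(spectrum.shape)
    rad = np.hypot(fx, fy)
    mask = (rad >= ring[0] * kc) & (rad <= ring[1] * kc)
    if prior_angle_deg is not None:
        ang = np.degrees(np.arctan2(fy, fx))
        diff = np.abs((ang - prior_angle_deg + 180.0) % 360.0 - 180.0)
        mask &= diff <= sector_halfwidth_deg
    if not mask.any():
        raise EstimationError(
            f"empty search mask: ring {ring} x k_c = {kc:.3f} with sector "
            f"{prior_angle_deg} +- {sector_halfwidth_deg} deg")
    mag = np.where(mask, np.abs(spectrum), -np.inf)
    iy, ix = np.unravel_index(int(np.argmax(mag)), mag.shape)
    neighborhood = mask[max(iy - 1, 0):iy + 2, max(ix - 1, 0):ix + 2]
    on_boundary = not neighborhood.all()
    return KVector(kx=float(fx[iy, ix]), ky=float(fy[iy, ix]),
                   precision="pixel", peak_value=float(mag[iy, ix]),
                   on_boundary=on_boundary)


def refine_k_subpixel(components: SpectralComponents, kc: float,
                      k_init: KVector, tol: float = 1e-3,
                      max_iter: int = 300) -> KVector:
    """Continuous sub-pixel refinement of the fringe k-vector.

    Maximizes ``|sum_k C(k) conj(L(k + k_hat))|`` where the zero order C
    and the phase-ramp-shifted low order L both carry the symmetrized
    weight ``H(k) H(k + k0)^2`` / ``H(k) H(k - k0)^2`` (k0 = the coarse
    peak).  With matched weights the sum is a weighted autocorrelation of
    the sample spectrum, so its magnitude peaks exactly at the true shift
    (Cauchy-Schwarz) instead of being dragged toward the scene's dominant
    low frequencies.  ``tol`` is the simplex tolerance in frequency-bin
    units.
    """
    shape = components.center.shape
    ny, nx = shape
    fx, fy = freq_grids(shape)
    rad = np.hypot(fx, fy)
    H = otf_at(rad, kc)
    k0 = (k_init.kx, k_init.ky)
    Hp = otf_at(np.hypot(fx + k0[0], fy + k0[1]), kc)
    Hm = otf_at(np.hypot(fx - k0[0], fy - k0[1]), kc)
    central_w = components.center * H * Hp ** 2
    side_spatial = ifft2c(components.low * H * Hm ** 2)
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny))

    def neg_mag(kv) -> float:
        ramp = np.exp(-2j * np.pi * (kv[0] * X + kv[1] * Y))
        shifted = fft2c(side_spatial * ramp)
        return -abs(np.sum(central_w * np.conj(shifted)))

    bin_size = 1.0 / max(ny, nx)
    x0 = np.array(k0)
    res = minimize(neg_mag, x0=x0, method="Nelder-Mead",
                   options={"xatol": tol * bin_size, "fatol": 0,
                            "maxiter": max_iter,
                            "initial_simplex": np.array(
                                [x0, x0 + [bin_size * 0.5, 0],
                                 x0 + [0, bin_size * 0.5]])})
    if not res.success:
        return KVector(kx=k0[0], ky=k0[1], precision="pixel",
                       peak_value=float(-res.fun))
    return KVector(kx=float(res.x[0]), ky=float(res.x[1]),
                   precision="subpixel", peak_value=float(-res.fun))


def estimate_modulation_phase(components: SpectralComponents, kc: float,
                              k: tuple[float, float],
                              otf_floor: float = 0.02,
                              dc_exclude_bins: float = 3.0
                              ) -> tuple[float, float]:
    """Modulation depth and global phase from the order overlap.

    The low order (separated with assumed m = 1 and first phase 0) equals
    ``m e^{i phi_1} S(k - k_theta) H(k)``.  Shifting it by ``+k`` and
    regressing against the zero order -- each multiplied by the *other*
    spectrum's OTF so both share the weight ``H(k) H(k + k_theta)`` --
    gives the complex factor ``m e^{i phi_1}`` directly.  A few bins
    around DC are excluded: camera offset and imperfect background
    subtraction concentrate there and would otherwise dominate the
    regression.  Returns ``(m, phi_1)``.
    """
    shape = components.center.shape
    ny, nx = shape
    fx, fy = freq_grids(shape)
    H = otf_at(np.hypot(fx, fy), kc)
    Hk = otf_at(np.hypot(fx + k[0], fy + k[1]), kc)
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny))
    ramp = np.exp(-2j * np.pi * (k[0] * X + k[1] * Y))
    side = fft2c(ifft2c(components.low) * ramp) * H
    cent = components.center * Hk
    mask = (Hk > otf_floor) & (H > otf_floor)
    mask &= np.hypot(fx, fy) >= dc_exclude_bins / max(ny, nx)
    den = np.sum(np.abs(cent[mask]) ** 2)
    if den == 0:
        raise EstimationError("empty OTF overlap for modulation estimate")
    cc = np.sum(side[mask] * np.conj(cent[mask])) / den
    return float(abs(cc)), float(np.angle(cc))


def estimate_illumination(images: Sequence[np.ndarray], otf: np.ndarray,
                          kc: float, prior_angle_deg: float,
                          sector_halfwidth_deg: float = 2.5,
                          ring: tuple[float, float] = (0.5, 1.1),
                          weight_ring: tuple[float, float] = (0.3, 1.0),
                          lockin_disc_bins: float = 12.0,
                          ) -> tuple[IlluminationEstimate, SpectralComponents]:
    """Full estimation chain for one angle's 3-phase image triplet.

    Runs the phase-step search, prior-constrained coarse peak search,
    sub-pixel k refinement, lock-in phase refinement and the modulation /
    global-phase regression.  Returns the estimate together with the
    orders separated using the refined phase differences (assumed m = 1;
    the true modulation scales the +-1 components and is reported in the
    estimate).
    """
    spectra = [fft2c(np.asarray(img, dtype=float)) for img in images]
    rad = np.hypot(*freq_grids(spectra[0].shape))
    w = build_weight(otf, kc, rad, ring=weight_ring)
    (phi1, phi2), trace = estimate_phase_differences(spectra, w)
    comps = separate_orders(spectra, (0.0, phi1, phi2), m=1.0)
    # the difference spectra are zero-order-free whatever the phases, so
    # the coarse peak search on them is immune to phase-step errors
    e1, e2 = difference_spectra(spectra)
    k0 = coarse_k_search(np.abs(e1) + np.abs(e2), kc, prior_angle_deg,
                         sector_halfwidth_deg, ring)
    kv = refine_k_subpixel(comps, kc, k0)
    phi1, phi2 = lockin_phase_differences(spectra, kv.as_tuple(),
                                          lockin_disc_bins)
    comps = separate_orders(spectra, (0.0, phi1, phi2), m=1.0)
    kv = refine_k_subpixel(comps, kc, kv)
    m, global_phase = estimate_modulation_phase(comps, kc, kv.as_tuple())
    comps.k_vector = kv
    comps.modulation = m
    cond = float(np.linalg.cond(mixing_matrix((0.0, phi1, phi2), 1.0)))
    est = IlluminationEstimate(
        k_vector=kv, phase_differences=(phi1, phi2),
        global_phase=global_phase, modulation=m,
        objective_trace={"phase_step": trace["phi_step"],
                         "objective_at_step": trace["objective_at_step"],
                         "coarse_peak": k0.as_tuple(),
                         "coarse_on_boundary": k0.on_boundary},
        condition_number=cond,
        converged=kv.precision == "subpixel")
    if m > 1.5:
        est.converged = False
    return est, comps


def baseline_estimate(images: Sequence[np.ndarray], otf: np.ndarray,
                      kc: float, notch_sigma: float = 0.1,
                      ) -> IlluminationEstimate:
    """Fixed-phase, notch-only reference estimator (the failure mode).

    Separates with the nominal 2 pi/3 phase ladder, suppresses the zero
    order with a Gaussian notch at DC, and takes the strongest remaining
    pixel in the whole half-plane as the fringe peak -- no difference
    trick, no prior sector, no sub-pixel refinement.  On well-exposed data
    this is the textbook approach; at very low SNR the first-order peak
    drowns and the global maximum lands on noise or leakage sidelobes.
    ``notch_sigma`` is in units of ``k_c``.
    """
    spectra = [fft2c(np.asarray(img, dtype=float)) for img in images]
    t = 2.0 * np.pi / 3.0
    comps = separate_orders(spectra, (0.0, t, 2.0 * t), m=1.0)
    fx, fy = freq_grids(spectra[0].shape)
    rad = np.hypot(fx, fy)
    notch = 1.0 - np.exp(-rad ** 2 / (2.0 * (notch_sigma * kc) ** 2))
    inband = rad <= 1.1 * kc
    mag = np.where(inband, np.abs(comps.low) * notch, -np.inf)
    iy, ix = np.unravel_index(int(np.argmax(mag)), mag.shape)
    kv = KVector(kx=float(fx[iy, ix]), ky=float(fy[iy, ix]),
                 precision="pixel", peak_value=float(mag[iy, ix]))
    return IlluminationEstimate(
        k_vector=kv, phase_differences=(t, 2.0 * t),
        global_phase=0.0, modulation=1.0,
        objective_trace={"method": "fixed-phase notch-only"})
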