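"""Forward model: synthetic scenes, sinusoidal excitation, optics and noise.

Renders the raw data a parallel-readout SIM instrument would record: a
fluorophore density map is multiplied by a sinusoidal excitation fringe,
blurred by the incoherent OTF of a circular pupil, and corrupted by Poisson
shot noise, Gaussian read noise and a constant camera offset.  Six (or
nine) such renders -- one per (angle, phase) -- are tiled into a full
sensor frame with small rigid jitter per sub-ROI, emulating galvo
vibration.  Everything is seeded, and the applied ground truth (k-vectors,
phases, modulation, shifts) is returned so downstream estimators can be
validated without instrument data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
from pydantic import BaseModel, Field, model_validator

from .fourier import fft2c, freq_grids, ifft2c, radial_freq, shift_spectrum
from .timing import scan_order

__all__ = [
    "Scene",
    "OpticsModel",
    "PatternSet",
    "NoiseModel",
    "FrameLayout",
    "SamplingError",
    "make_otf",
    "make_psf",
    "render_raw",
    "render_pattern_set",
    "assemble_frame",
    "simulate_dataset",
    "bead_scene",
    "mixed_scene",
    "amplitude_for_snr",
    "SimulationConfig",
]


class SamplingError(ValueError):
    """Raised when the optical cutoff exceeds the Nyquist frequency."""


@dataclass
class Scene:
    """Ground-truth fluorophore density map.

    ``intensity_map`` is in photons per pixel per unit exposure; all values
    must be finite and non-negative.
    """

    intensity_map: np.ndarray
    pixel_size: float  # nm / pixel
    emitters: Optional[np.ndarray] = None  # (n, 3) rows of (x, y, amplitude)

    def __post_init__(self) -> None:
        self.intensity_map = np.asarray(self.intensity_map, dtype=float)
        if self.intensity_map.ndim != 2:
            raise ValueError("intensity_map must be 2D")
        if not np.all(np.isfinite(self.intensity_map)):
            raise ValueError("intensity_map must be finite")
        if np.any(self.intensity_map < 0):
            raise ValueError("intensity_map must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity_map.shape


class OpticsModel(BaseModel):
    """Imaging-path parameters of the widefield detection optics."""

    numerical_aperture: float = Field(1.49, gt=0, le=1.7)
    emission_wavelength: float = Field(580.0, gt=300, lt=800)  # nm
    excitation_wavelength: float = Field(561.0, gt=300, lt=800)  # nm
    pixel_size: float = Field(65.0, gt=0)  # nm in sample space

    @property
    def cutoff_cycles_per_px(self) -> float:
        """Incoherent OTF cutoff k_c = 2 NA / lambda_em, in cycles/pixel."""
        return 2.0 * self.numerical_aperture / self.emission_wavelength \
            * self.pixel_size


class PatternSet(BaseModel):
    """Sinusoidal illumination patterns for one reconstruction group.

    ``n_angles`` fringe orientations x 3 phases with a nominal phase step
    of 2 pi / 3.  ``phase_offsets``, when set, holds the actual per-image
    phase (radians, one per (angle, phase)) so vibration-induced phase
    errors can be emulated; otherwise phases are exactly nominal.
    """

    n_angles: int = Field(2, ge=2, le=3)
    n_phases: int = 3
    angles: Sequence[float] = ()  # degrees
    period: float = Field(3.8, gt=2.0)  # pixels
    modulation: float = Field(0.9, gt=0, le=1.0)
    amplitude: float = Field(50.0, gt=0)  # I0, photons at unit scene density
    phase_offsets: Optional[Sequence[Sequence[float]]] = None

    @model_validator(mode="after")
    def _fill_angles(self) -> "PatternSet":
        if not self.angles:
            # 2 angles 90 deg apart, 3 angles 60 deg apart
            base = {2: (0.0, 90.0), 3: (10.0, 70.0, 130.0)}[self.n_angles]
            object.__setattr__(self, "angles", base)
        if len(self.angles) != self.n_angles:
            raise ValueError("angles length must equal n_angles")
        if self.n_phases != 3:
            raise ValueError("only 3-phase patterns are supported")
        return self

    @property
    def n_images(self) -> int:
        return self.n_angles * self.n_phases

    def k_vector(self, angle_index: int) -> tuple[float, float]:
        """Fringe k-vector in cycles/pixel; |k| = 1/period."""
        a = np.deg2rad(self.angles[angle_index])
        return (np.cos(a) / self.period, np.sin(a) / self.period)

    def phase(self, angle_index: int, phase_index: int) -> float:
        """Actual fringe phase of one image (radians)."""
        nominal = 2.0 * np.pi * phase_index / self.n_phases
        if self.phase_offsets is not None:
            return float(self.phase_offsets[angle_index][phase_index])
        return nominal

    def with_phase_jitter(self, sigma: float,
                          rng: np.random.Generator) -> "PatternSet":
        """Copy with per-image Gaussian phase errors added to the nominal
        2 pi/3 ladder (the signature of residual sub-image misregistration)."""
        offsets = [[2.0 * np.pi * p / self.n_phases
                    + float(rng.normal(0.0, sigma))
                    for p in range(self.n_phases)]
                   for _ in range(self.n_angles)]
        return self.model_copy(update={"phase_offsets": offsets})


class NoiseModel(BaseModel):
    """sCMOS noise approximation: Poisson shot noise, Gaussian read noise
    and a constant digitizer offset."""

    photon_scale: float = Field(1.0, gt=0)  # counts per photo-electron
    read_noise_sigma: float = Field(8.0, ge=0)  # counts
    baseline_offset: float = Field(100.0, ge=0)  # counts
    seed: int = 0


class FrameLayout(BaseModel):
    """2 x 3 grid of sub-ROI rectangles inside one full sensor frame.

    Rectangles are (row0, col0, height, width), 0-based half-open.
    ``scan_order`` maps pattern index -> grid position, following the
    center-outward rolling-readout orbit of the chosen sensor half.
    """

    frame_shape: tuple[int, int]
    subroi_shape: tuple[int, int]
    margin: int = Field(2, ge=0)
    sensor_half: str = "top"
    jitter_sigma: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _check_fit(self) -> "FrameLayout":
        fh, fw = self.frame_shape
        sh, sw = self.subroi_shape
        if 2 * sh + 3 * self.margin > fh or 3 * sw + 4 * self.margin > fw:
            raise ValueError(
                f"2x3 grid of {self.subroi_shape} sub-ROIs with margin "
                f"{self.margin} does not fit a {self.frame_shape} frame")
        return self

    @property
    def grid_positions(self) -> list[tuple[int, int]]:
        """Pattern-ordered grid positions P1..P6."""
        return scan_order(self.sensor_half)

    def rectangle(self, grid_row: int, grid_col: int) -> tuple[int, int, int, int]:
        """(row0, col0, h, w) of one grid cell; outer borders and the
        inter-ROI gaps all honor ``margin`` so jittered placements keep a
        guard band."""
        fh, fw = self.frame_shape
        sh, sw = self.subroi_shape
        # vertical slack beyond the two sub-ROI rows and outer margins
        row_gap = fh - 2 * sh - 2 * self.margin
        r0 = self.margin + grid_row * (sh + row_gap)
        c0 = self.margin + grid_col * (sw + self.margin)
        return (r0, c0, sh, sw)

    def rectangles(self) -> list[tuple[int, int, int, int]]:
        """Rectangles in pattern order P1..P6."""
        return [self.rectangle(r, c) for r, c in self.grid_positions]


def make_otf(optics: OpticsModel, shape: tuple[int, int]) -> np.ndarray:
    """Ideal incoherent 2D OTF of a circular pupil, DC-centered.

    OTF(rho) = (2/pi) (acos(rho) - rho sqrt(1 - rho^2)) for rho = k/k_c <= 1
    and 0 beyond -- the autocorrelation of the pupil disc.  Real-valued in
    [0, 1] with OTF(0) = 1.
    """
    if shape[0] < 16 or shape[1] < 16:
        raise ValueError("shape must be at least 16 x 16")
    kc = optics.cutoff_cycles_per_px
    if kc >= 0.5:
        raise SamplingError(
            f"OTF cutoff {kc:.3f} cycles/px is at or above Nyquist (0.5); "
            f"the scene is undersampled at pixel size "
            f"{optics.pixel_size:g} nm")
    return otf_at(radial_freq(shape), kc)


def otf_at(k_radial: np.ndarray, kc: float) -> np.ndarray:
    """Evaluate the circular-pupil incoherent OTF at given |k| values."""
    rho = np.clip(np.asarray(k_radial, dtype=float) / kc, 0.0, 1.0)
    otf = (2.0 / np.pi) * (np.arccos(rho) - rho * np.sqrt(1.0 - rho ** 2))
    otf[np.asarray(k_radial) >= kc] = 0.0
    return otf


def shifted_otf(optics: OpticsModel, shape: tuple[int, int],
                k: tuple[float, float], pixel_scale: float = 1.0) -> np.ndarray:
    """OTF evaluated at (k' + k): the passband of a shifted order, computed
    analytically on a (possibly upsampled) centered grid."""
    fx, fy = freq_grids(shape, d=pixel_scale)
    rad = np.hypot(fx + k[0], fy + k[1])
    return otf_at(rad, optics.cutoff_cycles_per_px)


def make_psf(optics: OpticsModel, shape: tuple[int, int],
             normalize: bool = True) -> np.ndarray:
    """Real-space widefield PSF (inverse transform of the OTF), centered at
    (n//2, m//2), normalized to sum 1."""
    otf = make_otf(optics, shape)
    psf = np.fft.fftshift(ifft2c(otf)).real
    psf = np.clip(psf, 0.0, None)
    if normalize:
        psf /= psf.sum()
    return psf


def blur(image: np.ndarray, otf: np.ndarray) -> np.ndarray:
    """Blur through a centered OTF; output clipped to be non-negative."""
    out = ifft2c(fft2c(image) * otf).real
    return np.clip(out, 0.0, None)


def render_raw(scene: Scene, optics: OpticsModel,
               k_vector: tuple[float, float], phase: float,
               modulation: float, amplitude: float,
               noise: Optional[NoiseModel] = None,
               exposure_scale: float = 1.0,
               rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Render one raw sub-image for a single (angle, phase) pattern.

    Noiseless model:  blur(scene * I0/2 * (1 + m cos(2 pi k.r + phi))).
    With ``noise``, Poisson shot noise is applied to the expected photon
    image, scaled to counts, and Gaussian read noise plus the camera offset
    are added.  Deterministic given ``rng`` (or ``noise.seed``).
    """
    if not 0.0 <= modulation <= 1.0:
        raise ValueError(f"modulation m = {modulation} outside [0, 1]")
    ny, nx = scene.shape
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny))
    kx, ky = k_vector
    fringe = 1.0 + modulation * np.cos(
        2.0 * np.pi * (kx * X + ky * Y) + phase)
    excited = scene.intensity_map * (amplitude / 2.0) * fringe
    otf = make_otf(optics, scene.shape)
    expected = blur(excited, otf) * exposure_scale
    if noise is None:
        return expected
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    counts = rng.poisson(expected).astype(float) * noise.photon_scale
    counts += rng.normal(0.0, noise.read_noise_sigma, size=counts.shape)
    counts += noise.baseline_offset
    return counts


def render_pattern_set(scene: Scene, optics: OpticsModel,
                       patterns: PatternSet,
                       noise: Optional[NoiseModel] = None,
                       exposure_scale: float = 1.0,
                       rng: Optional[np.random.Generator] = None
                       ) -> tuple[list[np.ndarray], list[tuple[int, int]]]:
    """Render all n_angles x 3 raw sub-images in pattern order.

    Returns (images, labels) with labels = (angle_index, phase_index).
    """
    if noise is not None and rng is None:
        rng = np.random.default_rng(noise.seed)
    images, labels = [], []
    for a in range(patterns.n_angles):
        for p in range(patterns.n_phases):
            images.append(render_raw(
                scene, optics, patterns.k_vector(a), patterns.phase(a, p),
                patterns.modulation, patterns.amplitude,
                noise=noise, exposure_scale=exposure_scale, rng=rng))
            labels.append((a, p))
    return images, labels


def assemble_frame(sub_images: Sequence[np.ndarray], layout: FrameLayout,
                   noise: Optional[NoiseModel] = None,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Place six pattern-ordered sub-images onto a full sensor frame.

    Each sub-ROI receives an independent rigid shift drawn from
    ``N(0, jitter_sigma)`` per axis: the integer part moves the rectangle,
    the fractional part is applied as an exact Fourier shift of the
    content.  Background pixels are set to the camera offset.  Returns
    ``(frame, shifts)`` with shifts of shape (6, 2) in (dy, dx) pixels.
    """
    rects = layout.rectangles()
    if len(sub_images) != len(rects):
        raise ValueError(
            f"expected {len(rects)} sub-images, got {len(sub_images)}")
    for i, img in enumerate(sub_images):
        if img.shape != tuple(layout.subroi_shape):
            raise ValueError(
                f"sub-image {i} shape {img.shape} does not match layout "
                f"sub-ROI shape {tuple(layout.subroi_shape)}")
    if rng is None:
        rng = np.random.default_rng(noise.seed if noise is not None else 0)
    offset = noise.baseline_offset if noise is not None else 0.0
    frame = np.full(layout.frame_shape, float(offset))

    shifts = np.zeros((len(rects), 2))
    if layout.jitter_sigma > 0:
        shifts = rng.normal(0.0, layout.jitter_sigma, size=shifts.shape)

    moved = []
    for (r0, c0, h, w), (dy, dx) in zip(rects, shifts):
        iy, ix = int(np.round(dy)), int(np.round(dx))
        moved.append((r0 + iy, c0 + ix, h, w, dy - iy, dx - ix))
    _check_disjoint(moved, layout.frame_shape)

    for img, (r0, c0, h, w, fy, fx) in zip(sub_images, moved):
        content = np.asarray(img, dtype=float)
        if fy != 0.0 or fx != 0.0:
            spec = np.fft.fft2(content)
            spec = _fourier_translate(spec, fy, fx)
            content = np.fft.ifft2(spec).real
        frame[r0:r0 + h, c0:c0 + w] = content
    return frame, shifts


def _fourier_translate(spec: np.ndarray, dy: float, dx: float) -> np.ndarray:
    ny, nx = spec.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    return spec * np.exp(-2j * np.pi * (fy * dy + fx * dx))


def _check_disjoint(moved, frame_shape) -> None:
    fh, fw = frame_shape
    for i, (r0, c0, h, w, *_rest) in enumerate(moved):
        if r0 < 0 or c0 < 0 or r0 + h > fh or c0 + w > fw:
            raise ValueError(f"sub-ROI {i + 1} falls outside the frame after "
                             f"jitter (rect origin {(r0, c0)})")
        for j in range(i + 1, len(moved)):
            r1, c1, h1, w1, *_ = moved[j]
            if r0 < r1 + h1 and r1 < r0 + h and c0 < c1 + w1 and c1 < c0 + w:
                raise ValueError(
                    f"sub-ROIs {i + 1} and {j + 1} overlap after jitter")


def bead_scene(shape: tuple[int, int], n_beads: int,
               rng: np.random.Generator, amplitude: float = 1.0,
               pixel_size: float = 65.0, border: int = 12,
               bead_sigma: float = 0.7) -> Scene:
    """Fluorosphere test-slide scene: a field of small Gaussian spots.

    ``bead_sigma`` (pixels) models the physical bead size -- a 100 nm
    sphere at 65 nm pixels is about 1.5 px across (sigma ~ 0.7 px).
    Finite-size emitters keep the scene spectrum band-limited the way a
    physical sample is; single-pixel impulses would carry artificial
    white spectral content beyond the Nyquist frequency.
    """
    ny, nx = shape
    img = np.zeros(shape)
    xs = np.round(rng.uniform(border, nx - border, n_beads))
    ys = np.round(rng.uniform(border, ny - border, n_beads))
    amps = amplitude * rng.uniform(0.6, 1.4, n_beads)
    for x, y, a in zip(xs, ys, amps):
        img[int(y), int(x)] += a
    if bead_sigma > 0:
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, bead_sigma, mode="constant")
    return Scene(img, pixel_size, emitters=np.column_stack([xs, ys, amps]))


def mixed_scene(shape: tuple[int, int], rng: np.random.Generator,
                density: float = 1.0, pixel_size: float = 65.0) -> Scene:
    """Structured test scene: many dim beads over smooth blobs.

    Gives the broadband spectral content (sharp points) plus extended
    structure (blobs) that real cellular fields show, so that spectral
    parameter estimators are exercised realistically.
    """
    ny, nx = shape
    n_beads = max(20, int(density * ny * nx / 400))
    beads = bead_scene(shape, n_beads, rng, amplitude=6.0,
                       pixel_size=pixel_size).intensity_map
    blobs = np.zeros(shape)
    for _ in range(max(3, int(density * 6))):
        cy, cx = rng.uniform(0.2, 0.8, 2) * (ny, nx)
        sig = rng.uniform(0.04, 0.12) * min(ny, nx)
        Y, X = np.ogrid[:ny, :nx]
        blobs += rng.uniform(0.3, 1.0) * np.exp(
            -((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sig ** 2))
    img = beads + blobs
    return Scene(img / img.mean(), pixel_size)


def amplitude_for_snr(scene: Scene, optics: OpticsModel,
                      noise: NoiseModel, target_snr_db: float,
                      signal_quantile: float = 0.75) -> float:
    """Pattern amplitude I0 that yields a target raw-image SNR in dB.

    SNR follows the background-region convention: Signal is the mean count
    excess of a bright (above-quantile) region over the background, and the
    noise power is the read-noise variance measured where the scene is
    empty, so SNR_dB = 10 log10(Signal / sigma_read^2).
    """
    if noise.read_noise_sigma <= 0:
        raise ValueError("read noise must be positive to define the target")
    otf = make_otf(optics, scene.shape)
    unit = blur(scene.intensity_map * 0.5, otf)  # I0 = 1, fringe-averaged
    bright = unit[unit > np.quantile(unit, signal_quantile)]
    mean_bright = bright.mean() * noise.photon_scale
    target_signal = noise.read_noise_sigma ** 2 * 10.0 ** (target_snr_db / 10)
    return float(target_signal / mean_bright)


class SimulationConfig(BaseModel):
    """Everything needed to generate a reproducible synthetic dataset."""

    optics: OpticsModel = OpticsModel()
    patterns: PatternSet = PatternSet()
    noise: NoiseModel = NoiseModel()
    scene_shape: tuple[int, int] = (128, 128)
    scene_kind: str = "mixed"  # "mixed" | "beads"
    n_beads: int = 60
    n_timepoints: int = 1
    target_snr_db: Optional[float] = None
    phase_jitter_sigma: float = 0.0  # rad
    layout_margin: int = 2
    jitter_sigma: float = 0.0  # px, sub-ROI placement jitter
    full_frames: bool = False  # write tiled frames instead of sub-stacks
    seed: int = 0


def simulate_dataset(config: SimulationConfig, out_dir: str | Path,
                     stem: str = "parsim_sim") -> tuple[Path, Path]:
    """Write a synthetic raw stack (16-bit TIFF) plus a JSON ground-truth
    sidecar.  Re-running with the same config reproduces both files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if config.scene_kind == "beads":
        scene = bead_scene(config.scene_shape, config.n_beads, rng,
                           pixel_size=config.optics.pixel_size)
    elif config.scene_kind == "mixed":
        scene = mixed_scene(config.scene_shape, rng,
                            pixel_size=config.optics.pixel_size)
    else:
        raise ValueError(f"unknown scene kind {config.scene_kind!r}")

    patterns = config.patterns
    if config.target_snr_db is not None:
        i0 = amplitude_for_snr(scene, config.optics, config.noise,
                               config.target_snr_db)
        patterns = patterns.model_copy(update={"amplitude": i0})

    pages, truth_frames = [], []
    for t in range(config.n_timepoints):
        pset = patterns
        if config.phase_jitter_sigma > 0:
            pset = patterns.with_phase_jitter(config.phase_jitter_sigma, rng)
        images, labels = render_pattern_set(
            scene, config.optics, pset, noise=config.noise, rng=rng)
        record = {
            "timepoint": t,
            "labels": [list(l) for l in labels],
            "k_vectors": [list(pset.k_vector(a))
                          for a in range(pset.n_angles)],
            "phases": [[pset.phase(a, p) for p in range(3)]
                       for a in range(pset.n_angles)],
            "modulation": pset.modulation,
            "amplitude": pset.amplitude,
        }
        if config.full_frames:
            if len(images) != 6:
                raise ValueError("full-frame tiling requires a 6-image "
                                 "(2-angle, 3-phase) pattern set")
            sh = config.scene_shape
            m = config.layout_margin
            layout = FrameLayout(
                frame_shape=(2 * sh[0] + 3 * m, 3 * sh[1] + 4 * m),
                subroi_shape=sh, margin=m,
                jitter_sigma=config.jitter_sigma)
            frame, shifts = assemble_frame(images, layout,
                                           noise=config.noise, rng=rng)
            pages.append(frame)
            record["applied_shifts"] = shifts.tolist()
            record["layout"] = json.loads(layout.model_dump_json())
        else:
            pages.extend(images)
        truth_frames.append(record)

    stack_path = out_dir / f"{stem}.tif"
    meta_path = out_dir / f"{stem}.json"
    if pages:
        data = np.clip(np.stack(pages), 0, 65535).astype(np.uint16)
    else:
        data = np.zeros((0,) + tuple(config.scene_shape), dtype=np.uint16)
    tifffile.imwrite(stack_path, data, photometric="minisblack")
    meta = {
        "config": json.loads(config.model_dump_json()),
        "scene_total": float(scene.intensity_map.sum()),
        "frames": truth_frames,
    }
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return stack_path, meta_path
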