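# Methods

`parsim` models a parallel acquisition-readout structured illumination
microscope (SIM): the timing algebra that lets a rolling-shutter sCMOS
expose some sensor rows while others read out, a seeded forward simulator
of the raw patterned sub-images such an instrument records, and a
reconstruction pipeline built for the very low raw SNR (down to about
−2 dB) that sub-millisecond pattern exposures produce. This note records
the models, the parameters that matter, the numerical choices, and what
the synthetic validation does and does not demonstrate.

## Acquisition timing model

A frame carries a 2×3 grid of sub-ROIs, each exposed under one
(angle, phase) of the illumination pattern set. The timing quantities are
the galvo dwell per sub-ROI `T_i`, the SLM switching duration `T_ii`
(the hard per-pattern lower bound, twice the nominal illumination window
because the ferroelectric modulator must reset polarity), the SLM
high-voltage window `T_iii`, and three trigger delays `T_D1, T_D2, T_D3`
(frame gap, exposure-to-scan delay, and the per-step galvo settling
buffer). The constraints checked by `timing.validate_plan` are:

1. `T_ii + T_D3 = T_i` — the dwell covers a full pattern cycle plus
   settling;
2. `T_ii ≤ T_i` — otherwise a pattern bleeds into the next sub-ROI
   (crosstalk);
3. `T_iii ≤ T_ii`;
4. `subroi_rows × t_row ≥ (n_subframes/2) × T_ii` — the staggered readout
   of half the patterns must fit under the exposure of the other half
   (`t_row` ≈ 9.74 µs per line on the reference camera);
5. `opened_rows ≥ 2 × subroi_rows`.

Derived analytics: minimum opened rows
`ceil(n_subframes · T_ii / t_row)` rounded **up** to the sensor's 4-row
granularity (this rounding uniquely reproduces the published 364 / 460 /
488 / 584 row budgets); raw and SIM frame rates floored to integer Hz;
spatio-temporal information flux = rate × pixels / 10⁶ (MPixels/s);
rolling cadence `frame_time × step / n_subframes`. Built-in plans carry
`subroi_rows = opened_rows / 2` — the row *budget*; a physically smaller
slit simply leaves margin.

## Forward model

One raw sub-image is

```
D = Poisson( blur( S · (I0/2)(1 + m cos(2π k·r + φ)) ) · exposure ) · g
    + N(0, σ_read) + offset
```

with `S` the fluorophore density (photons/pixel/exposure), `k` the fringe
vector in cycles/pixel (|k| = 1/period), `m` the modulation depth, `I0`
the amplitude, `g` the count gain. The blur kernel is the ideal incoherent
OTF of a circular pupil (the autocorrelation-of-the-disc "chat" function)
with cutoff `k_c = 2·NA/λ_em`; defaults NA 1.49, λ_em 580 nm, 65 nm pixels
give `k_c ≈ 0.334` cycles/pixel. Noise is the standard sCMOS
approximation — Poisson shot noise, Gaussian read noise (default σ = 8
counts), constant offset (default 100 counts). Frames are assembled by
placing six pattern-ordered sub-images on the 2×3 grid in the sensor
half's center-outward scan order, with independent rigid jitter per
sub-ROI (integer part moves the rectangle, fractional part is an exact
Fourier translation) emulating galvo vibration.

Raw-image SNR follows the background-region convention:
`SNR_dB = 10 log10(Signal / MSE_noise)` with `Signal` the mean count
excess of a structure region over the background mean and `MSE_noise` the
background variance. `amplitude_for_snr` inverts this to set `I0` for a
target SNR, which is how the −2 dB study conditions are produced.

### Synthetic scenes

* `mixed_scene` — smooth blobs (organelle-scale structure) plus many dim
  puncta; normalized to unit mean.
* `bead_scene` — a field of fluorospheres rendered as σ = 0.7 px Gaussian
  spots (a 100 nm sphere at 65 nm pixels). Finite emitter size matters:
  single-pixel impulses would carry white spectral power beyond the
  Nyquist frequency that aliases onto the fringe's second harmonic and
  biases phase estimation — an artifact of the fixture, not a property of
  real samples.

What the simulator does **not** emulate: out-of-focus background, sCMOS
fixed-pattern/row noise, photobleaching, sample motion during a pattern
set, polarization effects, or any 3D structure. Passing tests therefore
demonstrate correctness of the algorithms under the stated image model,
not performance on arbitrary instrument data.

## Preprocessing

Per sub-image: background subtraction (iterative 2.5 σ sigma-clipped
mean — unbiased for symmetric read noise plus sparse signal, unlike a
low-percentile statistic), Gaussian edge taper (border 16 px, σ 8 px;
interior pixels bit-identical) against spectral leakage, and an optional
Richardson–Lucy prefilter against the theoretical widefield PSF
(5 iterations when used standalone). Inside `reconstruct` the RL
prefilter defaults to **off**: RL is multiplicative and distorts the
linear three-phase mixing model that both parameter estimation and
spectral separation assume; on desk-scale fields it measurably biased
phase estimates. The knob stays in `ReconConfig` for contrast-boosting
use.

Registration: phase correlation with 100× upsampled refinement. Because a
fringe phase step is indistinguishable from a translation along `k`
(a 2π/3 step looks like a period/3 ≈ 1.3 px shift), shifts are estimated
on low-pass-filtered copies (σ 3 px, circular boundaries) and removed
from the originals by exact Fourier translation. The residual error floor
is set by demodulated high-frequency scene content — the super-resolution
information itself, which no filter can separate from a true shift; at
the instrument's 192-row sub-ROI size this floor is ≈ 0.08 px RMS at
0 dB.

## Illumination-parameter estimation

The chain, per angle triplet (all steps deterministic):

1. **Phase-step search.** The pairwise differences `D₂−D₁, D₃−D₁` cancel
   the zero order and any constant background exactly. Assuming the 1:2
   phase ladder, the weighted normalized cross-correlation magnitude of
   the two first orders separated from the differences is minimized over
   the step φ ∈ (π/3, π) — 64-point grid plus golden-section refinement.
   The weight `w(k)` is a 0.3–1.0 `k_c` ring times OTF². This 1-D search
   is used only as an initializer: extending the same objective to two
   independent phase differences is degenerate, because the two first
   orders of a real scene are never exactly independent (their intrinsic
   correlation C0 ≠ 0) and the 2-D minimizer reaches |corr| = 0 at a
   point displaced O(C0/E) from the truth. Every correction built from
   conjugate symmetry is structurally null (the difference-mixing matrix
   satisfies conj(A) = PAP), so the deviation information must come from
   elsewhere — step 4.
2. **Coarse peak search** on |D₂−D₁| + |D₃−D₁| (zero-order-free for any
   phase error) inside the ring 0.5–1.1 `k_c` intersected with a ±2.5°
   sector around the fringe angle loaded on the SLM. The prior sector
   shrinks the candidate set ≈ 70-fold and excludes the leakage sidelobes
   that defeat an unconstrained notch-filter search at low SNR.
3. **Sub-pixel k refinement** maximizes |Σ C(k)·conj(L(k+k̂))| over
   continuous k̂ (Nelder–Mead, tolerance 10⁻³ bin), where the zero order
   C and the phase-ramp-shifted low order L both carry the *symmetrized*
   weight `H(k)·H(k±k₀)²` built from the coarse peak k₀. With matched
   weights the sum is a weighted autocorrelation of the sample spectrum,
   so by Cauchy–Schwarz its magnitude peaks exactly at the true shift;
   with the naive one-sided weighting the scene's dominant low
   frequencies drag the maximum off by a measurable fraction of a bin.
4. **Lock-in phase refinement.** Each raw spectrum is shifted by +k̂
   (exact spatial phase ramp) and correlated against the widefield
   (phase-average) spectrum over a 12-bin disc at DC. The zero-order
   contribution is identical for the three images, so
   `cᵢ = K0 + A·e^{iφᵢ}` with common K0 and (real, positive) A, and the
   two phase differences follow in closed form from
   `R = (c₂−c₁)/(c₃−c₁) = (e^{ip₁}−1)/(e^{ip₂}−1)`:
   `tan(p₂/2) = sin(arg R)/(|R| − cos(arg R))`, `p₁ = p₂ + 2·arg R`.
   The residual bias (≈ 0.02–0.03 rad on the study scenes) comes from the
   high order leaking scene content at 2k into the disc; it vanishes for
   band-limited scenes.
5. **Separation and m/φ₁ regression.** Orders are separated by exact
   inversion of the mixing matrix rows `[1, (m/2)e^{+iφᵢ}, (m/2)e^{−iφᵢ}]`
   (convention: a `cos(2πk·r + φ)` fringe puts `e^{+iφ}` on the
   `S(k−k_θ)` order; condition number > 10⁶ is refused). Separating with
   m = 1 and first phase 0 leaves the low order equal to
   `m·e^{iφ₁}·S(k−k_θ)H(k)`; shifting it by +k̂ and regressing against
   the zero order — each factor multiplied by the *other's* OTF so both
   share the weight `H(k)H(k+k_θ)`, with a 3-bin DC disc excluded because
   camera offset and background residuals concentrate there — returns the
   complex factor `m·e^{iφ₁}` directly. Under heavy noise the regression
   attenuates m (≈ 0.65 measured for a true 0.8 at −2 dB); noiseless
   recovery is within 1 %. The attenuation is reported, not corrected.

The reference failure mode (`baseline_estimate`) is the textbook
approach: fixed 2π/3 phases, Gaussian notch at DC, strongest in-band
pixel wins — no difference trick, no prior, no refinement.

## Spectral fusion and deconvolution

All fusion happens on a 2× zero-padded grid (the conjugate-unpaired
Nyquist row/column of the original grid is dropped — it breaks Hermitian
symmetry when embedded, and the passband ends well below it). Orders are
moved to their true positions by exact phase-ramp shifts and normalized
by their estimated `m·e^{iφ₁}`. Step 1 is a generalized Wiener
combination, `Σ m_d·OTF_d·C_d / (Σ m_d²·OTF_d² + w²)` over every order of
every angle (shifted OTFs evaluated analytically; Wiener parameter
default 0.05), with Gaussian notches (σ 1.5 bins, depth 1) at the
residual zero-order positions ±k_θ. Step 2 multiplies by the ideal
apodization `W2 = max(0, 1 − |k|/k_ext)` with the extended cutoff
`k_ext = k_c + max|k_θ|`. The same combination applied to the OTFs,
apodized and normalized to 1 at DC, is the synthesized SIM OTF; its
inverse transform, cropped to a compact support and normalized to sum 1,
is the synthesized PSF — visibly non-circular, with sidelobes along the
pattern angles — used for the final Richardson–Lucy pass (default 10
iterations, reflective padding, flux-conserving).

Rolling reconstruction slides a one-pattern-set window by `step`
sub-images (output count `floor((n − set)/step) + 1`). Later windows
reuse the first window's k-vectors and re-estimate phases and modulation
per window (vibration perturbs phase far more than fringe period);
window-aligned rolling outputs are bit-identical to frame-by-frame
reconstruction by construction, and tested to be.

## Quantification

`measure_fwhm` fits a 1-D Gaussian (amplitude, center, σ, offset) to a
line profile and reports `2√(2 ln 2)·σ·pixel_size`. `track_stats`
projects frame-to-frame tip motion onto a running axis (PCA major axis of
a trailing 10-point window, oriented along the net displacement), labels
direction with a 0.5 px dead band, and reports velocities at the native
cadence and on a `step`-fold subsampled copy of the same track (step 25
maps a 7.35 ms cadence to 183.75 ms, the conventional-camera regime).

## Validation studies and their conditions

Fixed once in `parsim.studies` (chosen with the fixture design, seeds
supplied externally):

* **Field** 192×192 px — the instrument sub-ROI height, width scaled down
  from 676 columns for desk-scale runtime; noise σ_read = 8, offset 100;
  fringe period 3.8 px (|k| ≈ 0.79 k_c); m = 0.8.
* **Recovery study**: 100 two-angle stacks of fresh mixed scenes at
  −2 dB, per-image phase jitter σ = 0.3 rad (≈ the phase error of a
  0.2 px residual registration at this |k|). Reported: median k error in
  cycles/image-width, median worst phase-difference error, the same for
  the baseline, and the baseline/full k-error ratio. Typical outcome:
  k ≈ 0.02–0.03 (bound 0.05), phase ≈ 0.07–0.10 rad (bound 0.1),
  baseline ≈ 25× worse on k.
* **Bead study**: 150 beads per field at 0 dB, 2 angles (0°/90°);
  median FWHM ratio SR/widefield ≈ 0.33–0.45 (bound 0.6; ≈ 0.5 even with
  the final deconvolution disabled, i.e. the gain is carried by the
  fusion, not by RL sharpening).
* **Rolling study**: two consecutive pattern sets, step 3 vs step 6;
  the window-aligned outputs differ by exactly 0.

## Known limitations

* Phase-difference accuracy is floored by scene content at 2k_θ
  (≈ 0.02–0.03 rad on structured scenes); the Eq.-style 2-D correlation
  minimization cannot recover independent per-image phases at all (see
  above), which is why the lock-in stage exists.
* Modulation estimates attenuate under heavy noise and are flagged
  (`flagged_low_modulation`) below 0.15 rather than corrected.
* The global phase is referenced to the pixel-grid origin and is
  therefore exquisitely sensitive to k̂ error (δφ ≈ 2π·δk·r̄); expect
  ≈ 0.1 rad at the study noise levels.
* Reconstruction quality degrades gracefully at −2 dB (QC flags set,
  parameters may be attenuated); the resolution criterion is only claimed
  at ≥ 0 dB.
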