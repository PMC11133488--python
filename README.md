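# parsim

Parallel acquisition-readout structured illumination microscopy (SIM):
acquisition-timing analytics, a seeded forward simulator of raw patterned
sub-images, and an ultralow-SNR SIM reconstruction pipeline.

## The problem

Linear SIM multiplies the sample by a sinusoidal excitation fringe
`(I0/2)(1 + m cos(2π k_θ·r + φ))`, which folds sample frequencies from
`±k_θ` into the detection passband; reconstructing from three phases per
angle extends the cutoff from `k_c = 2·NA/λ` to `k_c + |k_θ|` — roughly a
twofold resolution gain. The frame rate of such a system is limited by the
rolling-shutter camera: conventionally, exposure must wait until every row
is open, so most of the readout time is wasted. A parallel
acquisition-readout scheme instead projects the patterned sub-images onto
a 2×3 grid of sensor sub-ROIs with a galvo pair, so the staggered readout
of the first half of the patterns runs *under* the exposure of the second
half. That buys a ~6× frame-rate increase — at the price of
sub-millisecond exposures whose raw SNR can drop below 0 dB, where
textbook SIM parameter estimation (notch filter, global spectral peak)
fails outright.

This package implements both halves:

* **`parsim.timing`** — the synchronization algebra: minimum opened sensor
  rows `⌈n·T_ii/t_row⌉₄`, raw and SIM frame rates, information flux,
  rolling cadence, acquisition counts, and constraint validation
  (`T_ii + T_D3 = T_i`, crosstalk, row budgets).
* **`parsim.simulate`** — the forward model: chat-function OTF, fringe
  excitation, Poisson + Gaussian sCMOS noise, 2×3 frame assembly with
  per-sub-ROI jitter, seeded dataset generation with ground-truth
  sidecars.
* **`parsim.prep`** — cropping, fringe-aware rigid registration,
  sigma-clipped background subtraction, edge apodization,
  Richardson–Lucy deconvolution.
* **`parsim.params`** — the low-SNR estimation chain: zero-order-free
  difference spectra, cross-correlation phase-step search, ring + prior
  sector coarse peak search, Cauchy–Schwarz-exact sub-pixel k refinement,
  closed-form lock-in phase differences, modulation / global-phase
  regression.
* **`parsim.recon`** — spectral separation, two-step Wiener + apodization
  fusion to the extended cutoff, synthesized SIM OTF/PSF, final RL
  deconvolution, rolling (sliding-window) reconstruction.
* **`parsim.metrics`** — SNR (`10·log10(Signal/MSE_noise)` from
  background/structure regions), Gaussian-fit FWHM, tip-track
  displacement/velocity statistics with downsampling comparison.
* **`parsim.studies`** — the seeded validation studies (parameter
  recovery at −2 dB, bead resolution benchmark, rolling consistency).

See `docs/methods.md` for the models, estimators and their assumptions.

## Worked example

Timing for the fast-modulator 0.2 ms configuration:

```sh
$ parsim timing --slm qxga --exposure-us 200
QXGA 0.2 ms: T_i/T_ii/T_iii = 649/589/210 us
  minimum opened rows : 364
  max raw framerate   : 1697 Hz
  SIM framerate       : 256 Hz
  plan valid
```

364 rows is the smallest opened sensor height that hides six 589 µs
pattern readouts behind the exposure at 9.74 µs/line; 256 Hz is the SIM
frame rate with the advised 649 µs galvo dwell (six sub-ROIs per frame).

Simulate and reconstruct a bead slide at 0 dB raw SNR:

```python
from parsim.studies import bead_resolution_study
r = bead_resolution_study(seed=7, snr_db=0.0)
print(r["fwhm_widefield_nm"], r["fwhm_sr_nm"], r["fwhm_ratio"])
```

prints (seed 7): widefield FWHM **213.6 nm**, reconstructed FWHM
**76.4 nm**, ratio **0.36** over 31 isolated beads, with the two fringe
vectors recovered at (0.26315, 0.00000) and (0.00005, 0.26322)
cycles/pixel against a true magnitude of 1/3.8 ≈ 0.26316 — i.e. the
illumination geometry is recovered to a few 10⁻⁵ cycles/pixel from
0 dB data and the reconstruction resolves well below the diffraction
limit.

The same pipeline is scriptable end-to-end from the shell:

```sh
parsim simulate --config sim.json --seed 3 --out sim/
parsim crop sim/parsim_sim.tif --subroi-shape 64 64 --out subs.tif
parsim register subs.tif --out reg.tif --report shifts.json
parsim reconstruct reg.tif sr.tif --rolling 3 --qc qc.json
parsim snr subs.tif --noise-rect 0 10 0 10 --signal-rect 20 44 20 44
```

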