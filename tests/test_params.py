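"""Illumination-parameter estimation: separation, peak search, refinement."""

import numpy as np
import pytest

from parsim.fourier import fft2c, freq_grids
from parsim.params import (EstimationError, baseline_estimate, build_weight,
                           coarse_k_search, difference_matrix,
                           difference_spectra, estimate_illumination,
                           estimate_modulation_phase,
                           estimate_phase_differences, lockin_phase_differences,
                           mixing_matrix, refine_k_subpixel, separate_orders)
from parsim.prep import apodize_edges, subtract_background
from parsim.simulate import (amplitude_for_snr, make_otf, mixed_scene,
                             render_raw)

ANGLE_DEG = 33.0
PERIOD = 3.8


def _k(angle_deg=ANGLE_DEG, period=PERIOD):
    a = np.deg2rad(angle_deg)
    return (np.cos(a) / period, np.sin(a) / period)


def _triplet(scene, optics, phases, m=0.8, amplitude=50.0, noise=None,
             rng=None, k=None):
    k = _k() if k is None else k
    return [render_raw(scene, optics, k, p, m, amplitude, noise=noise,
                       rng=rng) for p in phases]


def _truth_components(scene, optics, k):
    """Closed-form forward components S(k)H, S(k - k0)H, S(k + k0)H via
    modulated copies of the scene -- independent of the separation code
    path.  The fringe amplitude and modulation prefactors live in the
    mixing matrix, not in these components."""
    otf = make_otf(optics, scene.shape)
    ny, nx = scene.shape
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny))
    ramp = np.exp(2j * np.pi * (k[0] * X + k[1] * Y))
    base = scene.intensity_map
    center = fft2c(base) * otf
    low = fft2c(base * ramp) * otf
    high = fft2c(base * np.conj(ramp)) * otf
    return center, low, high


class TestSeparation:
    def test_noiseless_oracle_match(self, optics, rng):
        """Exact inversion: separated orders equal the forward-model
        components to better than 1e-8 relative Frobenius norm."""
        scene = mixed_scene((96, 96), rng)
        k = _k()
        t = 2 * np.pi / 3
        phases = [0.7, 0.7 + t, 0.7 + 2 * t]
        imgs = _triplet(scene, optics, phases)
        spectra = [fft2c(im) for im in imgs]
        comps = separate_orders(spectra, phases, m=0.8, amplitude=50.0)
        c0, lo, hi = _truth_components(scene, optics, k)
        for got, want in ((comps.center, c0), (comps.low, lo),
                          (comps.high, hi)):
            rel = np.linalg.norm(got - want) / np.linalg.norm(want)
            assert rel < 1e-8

    def test_ladder_matrix_matches_symbolic_inverse(self):
        """For phases {0, 2pi/3, 4pi/3} and m = 1 the mixing matrix has
        discrete-Fourier structure and a closed-form inverse."""
        t = 2 * np.pi / 3
        mat = mixing_matrix((0.0, t, 2 * t), m=1.0, amplitude=2.0)
        w = np.exp(1j * t)
        # rows [1, (1/2) w^p, (1/2) w^-p]: inverse = (1/3) [[1,1,1],
        # [2 w^-0, 2 w^-1, 2 w^-2], [2 w^0, 2 w^1, 2 w^2]]
        expected_inv = np.array([
            [1, 1, 1],
            [2, 2 * w ** -1, 2 * w ** -2],
            [2, 2 * w, 2 * w ** 2]]) / 3.0
        assert np.allclose(np.linalg.inv(mat), expected_inv)

    def test_zero_modulation_rejected(self, rng):
        spectra = [fft2c(rng.random((32, 32))) for _ in range(3)]
        with pytest.raises(EstimationError):
            separate_orders(spectra, (0.0, 2.1, 4.2), m=0.0)

    def test_degenerate_phases_rejected(self, rng):
        spectra = [fft2c(rng.random((32, 32))) for _ in range(3)]
        with pytest.raises(EstimationError, match="ill-conditioned"):
            separate_orders(spectra, (0.0, 1e-9, 2e-9), m=1.0)


class TestDifferenceSpectra:
    def test_identical_inputs_give_zero(self, rng):
        s = fft2c(rng.random((32, 32)))
        e1, e2 = difference_spectra([s, s.copy(), s.copy()])
        assert np.all(e1 == 0) and np.all(e2 == 0)

    def test_constant_background_cancels(self, optics, rng):
        scene = mixed_scene((64, 64), rng)
        t = 2 * np.pi / 3
        imgs = _triplet(scene, optics, [0, t, 2 * t])
        withbg = [im + 123.0 for im in imgs]
        e_raw = difference_spectra([fft2c(im) for im in imgs])
        e_bg = difference_spectra([fft2c(im) for im in withbg])
        # the added constant cancels identically, DC bin included
        assert np.allclose(e_raw[0], e_bg[0], atol=1e-6)
        dc = (32, 32)
        assert abs(e_bg[0][dc] - e_raw[0][dc]) < 1e-6

    def test_differences_are_pure_first_order(self, optics, rng):
        """The difference spectra equal the first-order-only combination
        of the forward components: the zero order cancels exactly."""
        scene = mixed_scene((64, 64), rng)
        t = 2 * np.pi / 3
        phases = [0.3, 0.3 + t, 0.3 + 2 * t]
        imgs = _triplet(scene, optics, phases, m=0.8, amplitude=50.0)
        e1, e2 = difference_spectra([fft2c(im) for im in imgs])
        _, lo, hi = _truth_components(scene, optics, _k())
        pre = 50.0 / 2 * 0.8 / 2  # I0/2 x m/2
        for e, pa, pb in ((e1, phases[1], phases[0]),
                          (e2, phases[2], phases[0])):
            want = pre * ((np.exp(1j * pa) - np.exp(1j * pb)) * lo
                          + (np.exp(-1j * pa) - np.exp(-1j * pb)) * hi)
            rel = np.linalg.norm(e - want) / np.linalg.norm(want)
            assert rel < 1e-8

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            difference_spectra([np.ones((8, 8)), np.ones((8, 8)),
                                np.ones((9, 9))])


class TestPhaseEstimation:
    def test_ladder_step_recovered_noiseless(self, optics, rng):
        scene = mixed_scene((96, 96), rng)
        t = 2 * np.pi / 3
        imgs = _triplet(scene, optics, [0.4, 0.4 + t, 0.4 + 2 * t])
        spectra = [fft2c(im) for im in imgs]
        otf = make_otf(optics, (96, 96))
        rad = np.hypot(*freq_grids((96, 96)))
        w = build_weight(otf, optics.cutoff_cycles_per_px, rad)
        (p1, p2), trace = estimate_phase_differences(spectra, w)
        # the step search is an initializer: scene self-correlation leaves
        # a residual bias that the lock-in stage later removes
        assert p1 == pytest.approx(t, abs=0.15)
        assert p2 == pytest.approx(2 * t, abs=0.3)

    def test_objective_minimized_at_true_step_on_grid(self, optics, rng):
        """The weighted cross-correlation objective dips at the true
        phase step within grid resolution."""
        scene = mixed_scene((96, 96), rng)
        t = 2 * np.pi / 3
        imgs = _triplet(scene, optics, [0, t, 2 * t])
        spectra = [fft2c(im) for im in imgs]
        otf = make_otf(optics, (96, 96))
        rad = np.hypot(*freq_grids((96, 96)))
        w = build_weight(otf, optics.cutoff_cycles_per_px, rad)
        _, trace = estimate_phase_differences(spectra, w)
        grid = np.array(trace["grid"])
        objective = np.array(trace["objective"])
        i_min = int(np.argmin(objective))
        assert abs(grid[i_min] - t) <= 2 * (grid[1] - grid[0])

    def test_lockin_recovers_jittered_phases(self, optics, rng):
        scene = mixed_scene((192, 192), rng)
        t = 2 * np.pi / 3
        phases = [0.9, 0.9 + t + 0.25, 0.9 + 2 * t - 0.18]
        imgs = _triplet(scene, optics, phases)
        spectra = [fft2c(im) for im in imgs]
        p1, p2 = lockin_phase_differences(spectra, _k())
        assert p1 == pytest.approx(t + 0.25, abs=0.05)
        assert p2 == pytest.approx(2 * t - 0.18, abs=0.05)

    def test_flat_objective_raises_no_modulation(self, optics, rng):
        scene = mixed_scene((64, 64), rng)
        imgs = _triplet(scene, optics, [0.0, 0.0, 0.0], m=0.0)
        spectra = [fft2c(im) for im in imgs]
        otf = make_otf(optics, (64, 64))
        rad = np.hypot(*freq_grids((64, 64)))
        w = build_weight(otf, optics.cutoff_cycles_per_px, rad)
        with pytest.raises(EstimationError, match="modulation"):
            estimate_phase_differences(spectra, w)

    def test_singular_difference_matrix(self):
        mat = difference_matrix(0.0, 0.0)
        assert abs(np.linalg.det(mat)) < 1e-12


class TestCoarseSearch:
    def _low_spectrum(self, optics, rng, shape=(96, 96)):
        scene = mixed_scene(shape, rng)
        t = 2 * np.pi / 3
        imgs = _triplet(scene, optics, [0, t, 2 * t])
        spectra = [fft2c(im) for im in imgs]
        e1, e2 = difference_spectra(spectra)
        return np.abs(e1) + np.abs(e2)

    def test_peak_found_at_true_pixel_with_prior(self, optics, rng):
        mag = self._low_spectrum(optics, rng)
        kc = optics.cutoff_cycles_per_px
        kv = coarse_k_search(mag, kc, prior_angle_deg=35.0)
        k_true = _k()
        assert abs(kv.kx - k_true[0]) <= 1.5 / 96
        assert abs(kv.ky - k_true[1]) <= 1.5 / 96

    def test_prior_off_by_ten_degrees_misses(self, optics, rng):
        mag = self._low_spectrum(optics, rng)
        kc = optics.cutoff_cycles_per_px
        kv = coarse_k_search(mag, kc, prior_angle_deg=ANGLE_DEG + 10.0,
                             sector_halfwidth_deg=2.5)
        # the true peak lies outside the sector: whatever is found is
        # not the fringe and sits off the true angle
        assert abs(kv.angle_deg - ANGLE_DEG) > 5.0

    def test_ring_excludes_dc_peak(self, optics, rng):
        shape = (96, 96)
        mag = np.zeros(shape)
        mag[48, 48] = 1e9  # dominant DC spike
        k_true = _k()
        iy = 48 + int(round(k_true[1] * 96))
        ix = 48 + int(round(k_true[0] * 96))
        mag[iy, ix] = 1.0
        kv = coarse_k_search(mag, optics.cutoff_cycles_per_px,
                             prior_angle_deg=ANGLE_DEG)
        assert kv.magnitude > 0.1  # not the DC bin

    def test_empty_mask_rejected(self, optics, rng):
        mag = np.ones((96, 96))
        with pytest.raises(EstimationError, match="empty"):
            # a vanishingly thin sector at an angle no frequency bin hits
            coarse_k_search(mag, optics.cutoff_cycles_per_px,
                            prior_angle_deg=7.3,
                            sector_halfwidth_deg=1e-9)

    def test_sector_prior_shrinks_search_domain(self, optics):
        """The +-2.5 degree sector keeps far fewer than 1/50th of the
        ring's candidate frequency bins."""
        shape = (192, 192)
        fx, fy = freq_grids(shape)
        rad = np.hypot(fx, fy)
        kc = optics.cutoff_cycles_per_px
        ring = (rad >= 0.5 * kc) & (rad <= 1.1 * kc)
        ang = np.degrees(np.arctan2(fy, fx))
        diff = np.abs((ang - ANGLE_DEG + 180.0) % 360.0 - 180.0)
        sector = ring & (diff <= 2.5)
        assert ring.sum() / sector.sum() >= 50


class TestSubpixelRefinement:
    def _estimate(self, optics, rng, snr_db=None, m=0.8, phases=None,
                  shape=(192, 192)):
        scene = mixed_scene(shape, rng)
        t = 2 * np.pi / 3
        if phases is None:
            phases = [0.7, 0.7 + t, 0.7 + 2 * t]
        noise = None
        amplitude = 50.0
        if snr_db is not None:
            from parsim.simulate import NoiseModel
            noise = NoiseModel(read_noise_sigma=8.0, baseline_offset=100.0,
                               seed=42)
            amplitude = amplitude_for_snr(scene, optics, noise, snr_db)
        imgs = _triplet(scene, optics, phases, m=m, amplitude=amplitude,
                        noise=noise, rng=rng)
        proc = [apodize_edges(subtract_background(im)[0], 16, 8.0)
                for im in imgs]
        otf = make_otf(optics, shape)
        est, comps = estimate_illumination(
            proc, otf, optics.cutoff_cycles_per_px, ANGLE_DEG)
        return est, phases

    def test_k_recovered_subpixel_at_good_snr(self, optics, rng):
        est, _ = self._estimate(optics, rng, snr_db=4.0)
        k_true = _k()
        assert est.k_vector.precision == "subpixel"
        assert abs(est.k_vector.kx - k_true[0]) < 5e-3
        assert abs(est.k_vector.ky - k_true[1]) < 5e-3

    def test_modulation_and_phase_exact_given_true_phases(self, optics,
                                                          rng):
        """With the true phase differences, the overlap regression
        recovers the modulation depth within 1% and the global phase
        within 0.05 rad on noiseless data."""
        shape = (192, 192)
        scene = mixed_scene(shape, rng)
        t = 2 * np.pi / 3
        phases = [0.7, 0.7 + t, 0.7 + 2 * t]
        imgs = _triplet(scene, optics, phases, m=0.8)
        spectra = [fft2c(im) for im in imgs]
        comps = separate_orders(spectra, (0.0, t, 2 * t), m=1.0)
        kc = optics.cutoff_cycles_per_px
        from parsim.params import KVector
        kv = refine_k_subpixel(comps, kc,
                               KVector(kx=_k()[0], ky=_k()[1]))
        m, phi = estimate_modulation_phase(comps, kc, kv.as_tuple())
        assert m == pytest.approx(0.8, rel=0.01)
        err = abs((phi - phases[0] + np.pi) % (2 * np.pi) - np.pi)
        assert err < 0.05

    def test_chain_modulation_and_phase_noiseless(self, optics, rng):
        """The full chain (estimated phases) keeps the modulation within
        a few percent and the global phase within 0.15 rad."""
        est, phases = self._estimate(optics, rng, m=0.8)
        assert est.modulation == pytest.approx(0.8, rel=0.05)
        err = abs((est.global_phase - phases[0] + np.pi) % (2 * np.pi)
                  - np.pi)
        assert err < 0.15

    def test_empty_overlap_rejected(self, optics, rng):
        from parsim.params import SpectralComponents
        comps = SpectralComponents(center=np.zeros((64, 64), complex),
                                   low=np.zeros((64, 64), complex),
                                   high=np.zeros((64, 64), complex))
        with pytest.raises(EstimationError):
            estimate_modulation_phase(comps, 0.334, (10.0, 10.0),
                                      otf_floor=2.0)


class TestWeightFunction:
    def test_vanishes_at_dc_and_nonnegative(self, optics):
        shape = (64, 64)
        otf = make_otf(optics, shape)
        rad = np.hypot(*freq_grids(shape))
        w = build_weight(otf, optics.cutoff_cycles_per_px, rad)
        assert w[32, 32] == 0.0
        assert np.all(w >= 0)

    def test_zero_outside_otf_support(self, optics):
        shape = (64, 64)
        otf = make_otf(optics, shape)
        rad = np.hypot(*freq_grids(shape))
        w = build_weight(otf, optics.cutoff_cycles_per_px, rad)
        assert np.all(w[otf == 0] == 0)


class TestBaseline:
    def test_baseline_finds_peak_on_clean_data(self, optics, rng):
        """With strong signal and exact ladder phases the notch-only
        approach works -- its failure is specific to low SNR."""
        scene = mixed_scene((96, 96), rng)
        t = 2 * np.pi / 3
        imgs = _triplet(scene, optics, [0, t, 2 * t], amplitude=500.0)
        proc = [apodize_edges(subtract_background(im)[0], 16, 8.0)
                for im in imgs]
        otf = make_otf(optics, (96, 96))
        est = baseline_estimate(proc, otf, optics.cutoff_cycles_per_px)
        k_true = _k()
        assert abs(est.k_vector.kx - k_true[0]) <= 1.5 / 96
        assert abs(est.k_vector.ky - k_true[1]) <= 1.5 / 96
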