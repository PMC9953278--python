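"""Despiking, SNV, baseline correction, and the Huber reference fit."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from cfrm.errors import DegenerateInputError, ParameterError
from cfrm.preprocess import (
    FitConfig,
    SpikeMask,
    average_background,
    detect_cosmic_rays,
    fit_to_reference,
    huber,
    huber_grad,
    local_median_mad,
    polynomial_baseline,
    preprocess_map,
    remove_cosmic_rays,
    snv,
)
from cfrm.simulate import SimConfig, inject_cosmic_rays, synth_cell_map
from cfrm.spectral_io import RamanMap, Spectrum, StageLabel, WavenumberAxis


class TestSnv:
    def test_hand_example(self, tiny_axis):
        out = snv(Spectrum(np.array([1.0, 2.0, 3.0]), tiny_axis))
        np.testing.assert_allclose(out.intensities, [-1.0, 0.0, 1.0], atol=1e-14)

    def test_zero_mean_unit_sd(self, rng, full_axis):
        out = snv(Spectrum(rng.uniform(0, 5, full_axis.m), full_axis))
        assert abs(out.intensities.mean()) < 1e-12
        assert abs(np.std(out.intensities, ddof=1) - 1.0) < 1e-12

    def test_constant_spectrum_degenerate(self, tiny_axis):
        with pytest.raises(DegenerateInputError):
            snv(Spectrum(np.array([5.0, 5.0, 5.0]), tiny_axis))

    def test_idempotent(self, rng, full_axis):
        s = Spectrum(rng.uniform(0, 5, full_axis.m), full_axis)
        once = snv(s)
        np.testing.assert_allclose(snv(once).intensities, once.intensities, atol=1e-12)


class TestHuber:
    @pytest.mark.parametrize("delta", [0.02, 0.1, 1.0])
    def test_closed_form_and_knot(self, delta):
        assert huber(0.0, delta) == 0.0
        # continuity at the knot: both branches give delta^2
        assert huber(delta, delta) == pytest.approx(delta**2, rel=1e-15)
        assert huber(2 * delta, delta) == pytest.approx(
            2 * delta * 2 * delta - delta**2, rel=1e-15
        )
        # equal one-sided derivatives 2*delta at |x| = delta
        eps = delta * 1e-7
        inner = (huber(delta, delta) - huber(delta - eps, delta)) / eps
        outer = (huber(delta + eps, delta) - huber(delta, delta)) / eps
        assert inner == pytest.approx(2 * delta, rel=1e-5)
        assert outer == pytest.approx(2 * delta, rel=1e-5)
        assert huber_grad(delta, delta) == pytest.approx(2 * delta)

    def test_specific_values(self):
        assert huber(0.02, 0.02) == pytest.approx(0.0004)
        assert huber(0.04, 0.02) == pytest.approx(0.0012)

    def test_even_and_monotone(self, rng):
        x = rng.uniform(-1, 1, 1000)
        np.testing.assert_allclose(huber(x, 0.1), huber(-x, 0.1))
        xs = np.sort(np.abs(x))
        assert np.all(np.diff(huber(xs, 0.1)) >= 0)

    def test_delta_must_be_positive(self):
        with pytest.raises(ParameterError):
            huber(1.0, 0.0)


@pytest.fixture(scope="module")
def spiked_map():
    cfg = SimConfig()
    clean, truth = synth_cell_map(StageLabel.METAPHASE, cfg, seed=101)
    spiked, spikes = inject_cosmic_rays(clean, cfg, seed=202)
    return clean, spiked, spikes


class TestDetect:
    def test_spike_free_map_empty_mask(self, spiked_map):
        clean, _, _ = spiked_map
        assert len(detect_cosmic_rays(clean)) == 0

    def test_single_synthetic_spike_found_exactly(self, spiked_map):
        clean, _, _ = spiked_map
        cube = clean.cube.copy()
        _, mad = local_median_mad(cube)
        cube[7, 9, 400] += 50 * mad[7, 9, 400]
        mask = detect_cosmic_rays(RamanMap(cube, clean.axis))
        assert mask.entries == ((7, 9, 400),)

    def test_recall_on_injected_spikes(self, spiked_map):
        _, spiked, spikes = spiked_map
        mask = detect_cosmic_rays(spiked)
        hits = {(r, c, t) for r, c, t, _ in spikes} & set(mask.entries)
        assert len(hits) >= 0.95 * len(spikes)

    def test_false_positive_rate_below_1e3(self, spiked_map):
        clean, _, _ = spiked_map
        n_entries = clean.cube.size
        assert len(detect_cosmic_rays(clean)) < 1e-3 * n_entries

    def test_window_must_be_small_odd(self, spiked_map):
        clean, _, _ = spiked_map
        with pytest.raises(ParameterError):
            detect_cosmic_rays(clean, spectral_window=4)
        with pytest.raises(ParameterError):
            detect_cosmic_rays(clean, spectral_window=clean.axis.m + 1)


class TestRemove:
    def test_empty_mask_identity(self, random_map_factory):
        m = random_map_factory(3, 3, 8)
        out = remove_cosmic_rays(m, SpikeMask((), m.cube.shape))
        np.testing.assert_array_equal(out.cube, m.cube)

    def test_midpoint_interpolation(self, rng):
        axis = WavenumberAxis(np.arange(20.0))
        cube = np.ones((1, 1, 20))
        cube[0, 0, 9], cube[0, 0, 10], cube[0, 0, 11] = 4.0, 99.0, 6.0
        out = remove_cosmic_rays(
            RamanMap(cube, axis), SpikeMask(((0, 0, 10),), cube.shape)
        )
        assert out.cube[0, 0, 10] == pytest.approx(5.0)

    def test_unflagged_entries_bit_identical(self, random_map_factory, rng):
        m = random_map_factory(4, 4, 30)
        flags = rng.random(m.cube.shape) < 0.05
        out = remove_cosmic_rays(m, SpikeMask.from_boolean(flags))
        np.testing.assert_array_equal(out.cube[~flags], m.cube[~flags])

    def test_fully_flagged_spectrum_degenerate(self, random_map_factory):
        m = random_map_factory(2, 2, 5)
        flags = np.zeros(m.cube.shape, dtype=bool)
        flags[0, 0, :] = True
        with pytest.raises(DegenerateInputError):
            remove_cosmic_rays(m, SpikeMask.from_boolean(flags))


class TestPolynomialBaseline:
    def test_polynomial_reproduces_itself(self, full_axis):
        x = np.linspace(-1, 1, full_axis.m)
        y = 1.0 + 0.5 * x - 0.3 * x**2 + 0.2 * x**3
        s = Spectrum(y + 2.0, full_axis)  # keep positive
        baseline, corrected = polynomial_baseline(s, order=3)
        assert np.max(np.abs(corrected.intensities)) < 1e-8 * np.max(np.abs(s.intensities))

    def test_peak_recovery_within_5pct(self, full_axis):
        x = np.linspace(-1, 1, full_axis.m)
        base = 2.0 + 0.4 * x + 0.3 * x**2
        peak_height = 10.0 * np.ptp(base)
        center = full_axis.m // 2
        peak = peak_height * np.exp(-0.5 * ((np.arange(full_axis.m) - center) / 8.0) ** 2)
        _, corrected = polynomial_baseline(Spectrum(base + peak, full_axis), order=2)
        assert corrected.intensities[center] == pytest.approx(peak_height, rel=0.05)

    def test_order_too_high_is_error(self, tiny_axis):
        with pytest.raises(ParameterError):
            polynomial_baseline(Spectrum(np.array([1.0, 2.0, 3.0]), tiny_axis), order=3)


def _distorted(reference, a_star, coeffs):
    x = np.linspace(-1, 1, reference.axis.m)
    p = np.polynomial.polynomial.polyval(x, coeffs)
    return Spectrum((reference.intensities - p) / a_star, reference.axis)


class TestFitToReference:
    def test_self_fit_is_exact(self, smooth_spectrum):
        fit = fit_to_reference(smooth_spectrum, smooth_spectrum)
        assert fit.loss < 1e-10
        assert fit.a == pytest.approx(1.0, abs=1e-4)
        assert np.all(np.abs(fit.coefficients) < 1e-4)

    def test_inverted_model_recovery(self, smooth_spectrum, rng):
        ref = smooth_spectrum
        coeffs = rng.uniform(-0.3, 0.3, 6)
        s = _distorted(ref, 0.5, coeffs)
        fit = fit_to_reference(s, ref, FitConfig(snv_first=False))
        rel = np.sqrt(np.mean((fit.fitted.intensities - ref.intensities) ** 2))
        assert rel / np.ptp(ref.intensities) < 0.01
        assert fit.a == pytest.approx(0.5, rel=1e-3)

    def test_huber_ignores_peaks_squared_does_not(self, smooth_spectrum, rng):
        ref = snv(smooth_spectrum)
        delta = 0.02
        m = ref.axis.m
        centers = np.linspace(150, m - 150, 5).astype(int)
        peaks = np.zeros(m)
        for c in centers:
            peaks += 50 * delta * np.exp(-0.5 * ((np.arange(m) - c) / 3.0) ** 2)
        s = Spectrum(ref.intensities + peaks, ref.axis)
        off_peak = np.ones(m, dtype=bool)
        for c in centers:
            off_peak[max(c - 15, 0) : c + 15] = False

        fits = {
            loss: fit_to_reference(s, ref, FitConfig(snv_first=False, loss=loss))
            for loss in ("huber", "squared")
        }
        rmse = {
            loss: np.sqrt(np.mean((f.fitted.intensities - ref.intensities)[off_peak] ** 2))
            for loss, f in fits.items()
        }
        assert rmse["huber"] < 0.02  # SNV units: sd of the reference is 1
        assert rmse["squared"] > rmse["huber"]

    def test_descent_from_start_point(self, smooth_spectrum, rng):
        ref = smooth_spectrum
        for _ in range(5):
            s = Spectrum(
                ref.intensities * rng.uniform(0.5, 2.0) + rng.normal(0, 0.05, ref.axis.m),
                ref.axis,
            )
            cfg = FitConfig()
            fit = fit_to_reference(s, ref, cfg)
            ys, yr = snv(s).intensities, snv(ref).intensities
            start_loss = 0.5 * np.sum(huber(ys - yr, cfg.delta))
            assert fit.loss <= start_loss + 1e-12

    def test_scale_equivariance(self, smooth_spectrum, rng):
        ref = smooth_spectrum
        s = _distorted(ref, 0.8, rng.uniform(-0.1, 0.1, 6))
        c = 3.0
        f1 = fit_to_reference(s, ref, FitConfig(snv_first=False))
        f2 = fit_to_reference(s.with_intensities(c * s.intensities), ref, FitConfig(snv_first=False))
        assert f2.a == pytest.approx(f1.a / c, rel=1e-3)
        np.testing.assert_allclose(
            f2.fitted.intensities, f1.fitted.intensities,
            atol=1e-6 * np.max(np.abs(f1.fitted.intensities)),
        )

    def test_matches_scipy_robust_least_squares(self, smooth_spectrum, rng):
        """Independent oracle: scipy's Huber-loss least squares on the same model."""
        ref = smooth_spectrum
        coeffs = rng.uniform(-0.2, 0.2, 6)
        s = _distorted(ref, 1.3, coeffs)
        noisy = Spectrum(
            s.intensities + rng.normal(0, 0.01 * np.ptp(s.intensities), s.axis.m), s.axis
        )
        cfg = FitConfig(snv_first=False)
        mine = fit_to_reference(noisy, ref, cfg)

        x = np.linspace(-1, 1, ref.axis.m)
        v = np.polynomial.polynomial.polyvander(x, cfg.n)

        def resid(theta):
            return theta[0] * noisy.intensities + v @ theta[1:] - ref.intensities

        x0 = np.zeros(cfg.n + 2)
        x0[0] = 1.0
        oracle = least_squares(resid, x0, loss="huber", f_scale=cfg.delta)
        fitted_oracle = oracle.x[0] * noisy.intensities + v @ oracle.x[1:]
        scale = np.ptp(ref.intensities)
        np.testing.assert_allclose(
            mine.fitted.intensities / scale, fitted_oracle / scale, atol=1e-4
        )


class TestAverageBackground:
    def test_single_pixel(self, random_map_factory):
        m = random_map_factory(3, 3, 6)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        out = average_background([m], [mask])
        np.testing.assert_array_equal(out.intensities, m.cube[1, 2])

    def test_two_pixel_mean_and_oracle(self, random_map_factory, rng):
        m = random_map_factory(4, 4, 6)
        mask = rng.random((4, 4)) < 0.4
        if not mask.any():
            mask[0, 0] = True
        out = average_background([m], [mask])
        acc = np.zeros(6)
        n = 0
        for r in range(4):
            for c in range(4):
                if mask[r, c]:
                    acc += m.cube[r, c]
                    n += 1
        np.testing.assert_allclose(out.intensities, acc / n)

    def test_empty_union_degenerate(self, random_map_factory):
        m = random_map_factory(2, 2, 4)
        with pytest.raises(DegenerateInputError):
            average_background([m], [np.zeros((2, 2), dtype=bool)])


class TestPreprocessMap:
    def test_reference_map_is_fixed_point(self, smooth_spectrum):
        cube = np.tile(smooth_spectrum.intensities, (4, 4, 1))
        m = RamanMap(cube, smooth_spectrum.axis)
        res = preprocess_map(m, smooth_spectrum, FitConfig(snv_first=False))
        np.testing.assert_allclose(res.map.cube, m.cube, atol=1e-6)
        assert len(res.fits) == 16

    def test_full_map_distortion_recovery(self, smooth_spectrum, rng):
        ref = smooth_spectrum
        h = w = 6
        cube = np.empty((h, w, ref.axis.m))
        for r in range(h):
            for c in range(w):
                cube[r, c] = _distorted(
                    ref, rng.uniform(0.7, 1.4), rng.uniform(-0.2, 0.2, 6)
                ).intensities
        res = preprocess_map(RamanMap(cube, ref.axis), ref, FitConfig(snv_first=False), despike=False)
        rel = [
            np.sqrt(np.mean((f.fitted.intensities - ref.intensities) ** 2))
            / np.ptp(ref.intensities)
            for f in res.fits
        ]
        assert np.median(rel) < 0.02
        assert len(res.fits) == h * w
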