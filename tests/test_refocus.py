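"""Angular-spectrum propagation, autofocus, calibration, three-depth."""

import numpy as np
import pytest

from holocyte.config import OpticsConfig
from holocyte.refocus import (CellCrop, FocusCalibration, amplitude_variance,
                              autofocus, calibrate_focus, divide_background,
                              propagate, refocus_cell, thin_object_phase)
from holocyte.simulate import CellSpec, make_cell_phase

WL = 0.640
PX = 0.203


def focused_cell_field(phase=2.0, radius=4.0, size=96):
    spec = CellSpec(center_frame=0, x_center=0, radius_um=radius,
                    peak_phase_rad=phase)
    return np.exp(1j * make_cell_phase(spec, PX, (size, size)))


def band_limit(field):
    return propagate(field, 0.0, WL, PX)


class TestPropagate:
    def test_zero_distance_is_identity_on_bandlimited_input(self):
        u = band_limit(focused_cell_field())
        np.testing.assert_allclose(propagate(u, 0.0, WL, PX), u, atol=1e-12)

    def test_round_trip_restores_bandlimited_field(self):
        u = band_limit(focused_cell_field())
        back = propagate(propagate(u, 7.3, WL, PX), -7.3, WL, PX)
        assert np.abs(back - u).max() < 1e-10

    def test_parseval_energy_conserved(self):
        u = band_limit(focused_cell_field())
        e0 = np.sum(np.abs(u) ** 2)
        e1 = np.sum(np.abs(propagate(u, 11.0, WL, PX)) ** 2)
        assert abs(e1 - e0) / e0 < 1e-9

    @pytest.mark.parametrize("d_um", [2.0, 4.0])
    def test_gaussian_beam_width_law(self, d_um):
        # closed-form oracle: w(d) = w0*sqrt(1 + (lambda*d/(pi*w0^2))^2)
        w0 = 1.5
        n = 128
        y = (np.arange(n) - n / 2)[:, None] * PX
        x = (np.arange(n) - n / 2)[None, :] * PX
        u = np.exp(-(x ** 2 + y ** 2) / w0 ** 2)
        up = propagate(u, d_um, WL, PX)
        intensity = np.abs(up) ** 2
        # 1/e^2 width from the second moment: <x^2> = w^2/4
        var_x = float((intensity * x ** 2).sum() / intensity.sum())
        w_measured = 2.0 * np.sqrt(var_x)
        w_expected = w0 * np.sqrt(1 + (WL * d_um / (np.pi * w0 ** 2)) ** 2)
        assert w_measured == pytest.approx(w_expected, rel=0.02)


class TestDivideBackground:
    def test_identical_fields_give_unit_quotient(self):
        f = focused_cell_field()
        crop = CellCrop(f, f, PX)
        q = divide_background(crop)
        np.testing.assert_allclose(q, 1.0, atol=1e-12)

    def test_constant_phase_offset_recovered_exactly(self):
        bg = focused_cell_field(phase=0.7)
        crop = CellCrop(bg * np.exp(1j * 1.234), bg, PX)
        np.testing.assert_allclose(np.angle(divide_background(crop)), 1.234,
                                   atol=1e-12)

    def test_near_zero_background_floored(self):
        bg = np.ones((16, 16), dtype=complex)
        bg[3, 3] = 1e-12
        crop = CellCrop(np.ones((16, 16), dtype=complex), bg, PX)
        q = divide_background(crop)
        assert np.isfinite(q).all()


class TestAmplitudeVariance:
    def test_constant_amplitude_zero(self):
        assert amplitude_variance(np.exp(1j * np.random.default_rng(0)
                                         .normal(size=(8, 8)))) == pytest.approx(0.0)

    def test_hand_variance(self):
        field = np.array([1.0, 1.0, 3.0, 3.0], dtype=complex)
        assert amplitude_variance(field) == pytest.approx(1.0)

    def test_global_phase_invariance(self):
        u = focused_cell_field()
        assert amplitude_variance(u * np.exp(1j * 0.9)) == pytest.approx(
            amplitude_variance(u))


class TestAutofocus:
    def test_grid_spacing(self):
        _, dists, _ = autofocus(np.ones((8, 8), dtype=complex), WL, PX)
        assert len(dists) == 32
        assert dists[1] - dists[0] == pytest.approx(48.0 / 31.0)

    def test_in_focus_object_prefers_zero(self):
        u = band_limit(focused_cell_field())
        d, dists, _ = autofocus(u, WL, PX)
        assert abs(d) <= (dists[1] - dists[0]) / 2 + 1e-9

    @pytest.mark.parametrize("d0", [-15.0, -6.0, 8.0, 18.0])
    def test_defocused_object_recovered_within_grid_step(self, d0):
        u = propagate(focused_cell_field(), d0, WL, PX)
        d, dists, _ = autofocus(u, WL, PX)
        assert abs(d - (-d0)) <= (dists[1] - dists[0]) + 1e-9


class TestCalibration:
    def test_exact_quadratic_recovered(self):
        x = np.linspace(0, 4096, 40)
        d = 2e-6 * x ** 2 - 0.005 * x + 3.0
        calib = calibrate_focus(list(zip(x, d)))
        assert calib.coeffs == pytest.approx((2e-6, -0.005, 3.0), abs=1e-9)
        assert calib.residual_std == pytest.approx(0.0, abs=1e-9)

    def test_constant_distance_gives_flat_curve(self):
        x = np.linspace(0, 4096, 20)
        calib = calibrate_focus([(xi, 5.5) for xi in x])
        a, b, c = calib.coeffs
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-9)
        assert c == pytest.approx(5.5)

    def test_insufficient_cells_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            calibrate_focus([(0, 1.0), (10, 2.0)])

    def test_noisy_recovery_within_three_standard_errors(self):
        # Monte-Carlo: 128 cells, 1 um Gaussian jitter, pooled over seeds
        truth = np.array([2e-6, -0.005, 3.0])
        n_seeds, n_cells, sigma = 100, 128, 1.0
        estimates, stds = [], []
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 4096, size=n_cells)
            d = truth[0] * x ** 2 + truth[1] * x + truth[2] \
                + rng.normal(0, sigma, size=n_cells)
            calib = calibrate_focus(list(zip(x, d)))
            estimates.append(calib.coeffs)
            stds.append(calib.residual_std)
        est = np.array(estimates)
        # standard error of each coefficient from the design matrix
        xg = np.random.default_rng(0).uniform(0, 4096, size=n_cells)
        X = np.vander(xg, 3)
        se = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        pooled_se = se / np.sqrt(n_seeds)
        assert np.all(np.abs(est.mean(axis=0) - truth) < 3 * pooled_se)
        assert np.mean(stds) == pytest.approx(sigma, rel=0.20)


class TestThreeDepthRefocus:
    def _crop(self, d_true):
        u = focused_cell_field()
        cell = propagate(u, d_true, WL, PX)
        return CellCrop(cell, np.ones_like(cell), PX, x_full=2000)

    def test_zero_spread_selects_middle_depth(self):
        crop = self._crop(d_true=5.0)
        calib = FocusCalibration(coeffs=(0.0, 0.0, -5.0), residual_std=0.0,
                                 n_cells_used=128)
        ref = refocus_cell(crop, calib, WL)
        assert ref.distance_um == pytest.approx(-5.0)
        assert len(set(np.round(ref.candidates_um, 9))) == 1

    def test_on_curve_cell_selects_middle(self):
        crop = self._crop(d_true=5.0)
        calib = FocusCalibration(coeffs=(0.0, 0.0, -5.0), residual_std=1.5,
                                 n_cells_used=128)
        ref = refocus_cell(crop, calib, WL)
        assert ref.distance_um == pytest.approx(-5.0)
        assert ref.variances[1] == ref.variances.min()

    def test_refinement_never_worse_than_calibrated_depth(self):
        for d_true, d_cal in [(4.0, -3.0), (9.0, -10.5), (14.0, -12.0)]:
            crop = self._crop(d_true)
            calib = FocusCalibration(coeffs=(0.0, 0.0, d_cal),
                                     residual_std=1.0, n_cells_used=128)
            ref = refocus_cell(crop, calib, WL)
            assert ref.variances.min() <= ref.variances[1] + 1e-15

    def test_refocused_phase_matches_truth_ssim(self):
        from holocyte.evaluation import ssim

        spec = CellSpec(center_frame=0, x_center=0, radius_um=4.0,
                        peak_phase_rad=2.0)
        truth_img = make_cell_phase(spec, PX, (96, 96))
        crop = self._crop(d_true=6.0)
        calib = FocusCalibration(coeffs=(0.0, 0.0, -6.0), residual_std=0.5,
                                 n_cells_used=128)
        ref = refocus_cell(crop, calib, WL)
        assert ssim(ref.phase, truth_img) > 0.98

    def test_divide_then_propagate_matches_paper_order(self):
        crop = self._crop(d_true=7.0)
        calib = FocusCalibration(coeffs=(0.0, 0.0, -7.0), residual_std=0.8,
                                 n_cells_used=128)
        a = refocus_cell(crop, calib, WL, propagate_before_divide=False)
        b = refocus_cell(crop, calib, WL, propagate_before_divide=True)
        assert a.distance_um == b.distance_um
        assert np.abs(a.phase - b.phase).max() < 1e-3


def test_thin_object_phase_branch():
    # delays up to 3*pi/2 come back on the nonnegative branch; small
    # negative excursions (ringing, noise) are preserved
    field = np.exp(1j * np.array([-0.3, 0.0, 2.0, 3.6, 4.5]))
    np.testing.assert_allclose(thin_object_phase(field),
                               [-0.3, 0.0, 2.0, 3.6, 4.5], atol=1e-12)
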