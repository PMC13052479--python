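"""Per-cell quantification: offsets, masks, measurements, filtering."""

import numpy as np
import pytest
from scipy.ndimage import rotate

from holocyte.config import OpticsConfig
from holocyte.morphology import (CellMorphology, NoObjectError, RBCFilter,
                                 cell_mask, corner_offset, filter_cell,
                                 measure)

PX = 0.203


def disk_image(radius_px, value=1.0, size=96, ratio=1.0):
    """Phase image of an ellipse with axes radius_px x radius_px/ratio."""
    y, x = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2
    r = np.sqrt(((y - cy) / (radius_px / ratio)) ** 2
                + ((x - cx) / radius_px) ** 2)
    return np.where(r <= 1.0, value, 0.0)


class TestCornerOffset:
    def test_constant_image(self):
        assert corner_offset(np.full((32, 32), 1.7)) == pytest.approx(1.7)

    def test_four_uniform_corners_average(self):
        img = np.zeros((32, 32))
        img[:8, :8] = 1.0
        img[:8, -8:] = 2.0
        img[-8:, :8] = 3.0
        img[-8:, -8:] = 4.0
        assert corner_offset(img) == pytest.approx(2.5)

    def test_linear_ramp_matches_block_means(self):
        img = np.linspace(0, 5, 64)[None, :] * np.ones((64, 1))
        expected = np.mean([img[:8, :8].mean(), img[:8, -8:].mean(),
                            img[-8:, :8].mean(), img[-8:, -8:].mean()])
        assert corner_offset(img) == pytest.approx(expected)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            corner_offset(np.zeros((10, 10)))


class TestCellMask:
    def test_clean_disk_support_recovered(self):
        img = disk_image(20)
        mask = cell_mask(img, threshold=0.3, opening_radius=0)
        np.testing.assert_array_equal(mask, img > 0.3)

    def test_isolated_spikes_removed_by_opening(self):
        img = disk_image(20)
        rng = np.random.default_rng(0)
        for _ in range(10):
            y, x = rng.integers(0, 96, size=2)
            if img[y, x] == 0.0 and y > 60:
                img[y, x] = 2.0
        mask = cell_mask(img, threshold=0.3, opening_radius=1)
        assert mask.sum() <= (disk_image(20) > 0.3).sum()
        assert not mask[70:, :].any() or mask[70:, :].sum() == 0

    def test_subthreshold_image_raises(self):
        with pytest.raises(NoObjectError):
            cell_mask(np.full((96, 96), 0.1), threshold=0.3)

    def test_largest_component_kept(self):
        img = disk_image(20) + np.roll(disk_image(6), 40, axis=1)
        mask = cell_mask(img, threshold=0.3, opening_radius=0)
        assert mask.sum() == pytest.approx((disk_image(20) > 0.3).sum(), abs=2)


class TestMeasure:
    def test_opl_scale_phi_2pi_equals_lambda(self):
        cfg = OpticsConfig()
        mask = disk_image(10) > 0.5
        img = np.where(mask, 2 * np.pi, 0.0)
        m = measure(img, mask, cfg)
        assert m.mean_opl_um == pytest.approx(cfg.wavelength_um)

    def test_disk_area_and_ov_closed_form(self):
        # uniform disk phi0 = 1 rad, R = 20 px of 0.203 um
        cfg = OpticsConfig()
        img = disk_image(20)
        mask = img > 0.3
        m = measure(img, mask, cfg)
        area_true = np.pi * (20 * PX) ** 2
        assert m.area_um2 == pytest.approx(area_true, rel=0.03)
        ov_true = area_true * 1.0 * cfg.wavelength_um / (2 * np.pi)
        assert m.ov_um3 == pytest.approx(ov_true, rel=0.03)

    def test_circle_eccentricity_and_circularity(self):
        m = measure(disk_image(20), disk_image(20) > 0.3, OpticsConfig())
        assert m.eccentricity < 0.05
        assert 0.95 <= m.circularity <= 1.05

    def test_two_to_one_ellipse_eccentricity(self):
        img = disk_image(30, ratio=2.0)
        m = measure(img, img > 0.3, OpticsConfig())
        assert m.eccentricity == pytest.approx(np.sqrt(3) / 2, abs=0.02)

    @pytest.mark.parametrize("angle", [0, 30, 90])
    def test_eccentricity_rotation_invariant(self, angle):
        img = disk_image(26, ratio=1.6)
        ref = measure(img, img > 0.3, OpticsConfig()).eccentricity
        rot = rotate(img, angle, reshape=False, order=1)
        m = measure(rot, rot > 0.3, OpticsConfig())
        assert m.eccentricity == pytest.approx(ref, abs=0.02)

    @pytest.mark.parametrize("radius", [10, 20, 40])
    def test_circularity_approaches_one_with_radius(self, radius):
        img = disk_image(radius, size=128)
        m = measure(img, img > 0.3, OpticsConfig())
        assert abs(m.circularity - 1.0) < 0.05

    def test_ov_scales_with_phase_and_pixel_area(self):
        cfg = OpticsConfig()
        img = disk_image(20)
        mask = img > 0.3
        m1 = measure(img, mask, cfg)
        m2 = measure(2 * img, mask, cfg)
        assert m2.ov_um3 == pytest.approx(2 * m1.ov_um3)
        m4 = measure(img, mask, cfg, pixel_um=2 * PX)
        assert m4.area_um2 == pytest.approx(4 * m1.area_um2)
        assert m4.ov_um3 == pytest.approx(4 * m1.ov_um3)

    def test_ov_identity_with_mean_opl(self):
        cfg = OpticsConfig()
        rng = np.random.default_rng(2)
        img = disk_image(20) * rng.uniform(0.5, 1.5, size=(96, 96))
        mask = disk_image(20) > 0.3
        m = measure(img, mask, cfg)
        dA = cfg.pixel_um ** 2
        assert m.ov_um3 == pytest.approx(m.mean_opl_um * m.n_pixels * dA)

    def test_printed_circularity_form(self):
        img = disk_image(20)
        m = measure(img, img > 0.3, OpticsConfig(),
                    circularity_printed_form=True)
        # 4*pi*C^2/A evaluates to ~(4*pi)^2 ~ 157.9 for a circle
        assert m.circularity == pytest.approx(16 * np.pi ** 2, rel=0.1)

    def test_single_pixel_mask_degenerate(self):
        mask = np.zeros((96, 96), dtype=bool)
        mask[48, 48] = True
        m = measure(np.ones((96, 96)), mask, OpticsConfig())
        assert m.degenerate and m.eccentricity == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(NoObjectError):
            measure(np.ones((96, 96)), np.zeros((96, 96), dtype=bool),
                    OpticsConfig())


class TestFilter:
    def _m(self, **kwargs):
        base = dict(area_um2=45.0, ov_um3=12.0, mean_opl_um=0.25,
                    eccentricity=0.3, circularity=0.95, perimeter_um=24.0,
                    n_pixels=1000, degenerate=False)
        base.update(kwargs)
        return CellMorphology(**base)

    def test_mid_range_accepted(self):
        assert filter_cell(self._m(), RBCFilter())

    def test_out_of_range_rejected(self):
        assert not filter_cell(self._m(area_um2=120.0), RBCFilter())
        assert not filter_cell(self._m(ov_um3=5.0), RBCFilter())
        assert not filter_cell(self._m(eccentricity=0.95), RBCFilter())
        assert not filter_cell(self._m(circularity=0.2), RBCFilter())

    def test_bounds_are_closed_intervals(self):
        f = RBCFilter()
        assert filter_cell(self._m(area_um2=f.area_um2[0]), f)
        assert filter_cell(self._m(area_um2=f.area_um2[1]), f)
        assert filter_cell(self._m(eccentricity=f.eccentricity_max), f)
        assert filter_cell(self._m(circularity=f.circularity_min), f)

    def test_degenerate_rejected(self):
        assert not filter_cell(self._m(degenerate=True), RBCFilter())

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            RBCFilter(area_um2=(90.0, 20.0))
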