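"""Negative correction, masking and symmetry-based gap filling."""

import numpy as np
import pytest

import fibrilsaxs as fs
from fibrilsaxs.errors import ValidationError
from fibrilsaxs.geometry import radial_coordinate


def pat(arr, mask=None):
    arr = np.asarray(arr, float)
    if mask is None:
        mask = np.isfinite(arr)
    return fs.Pattern(arr, mask, "test")


class TestCorrectNegative:
    def test_shifts_by_global_minimum(self):
        p = fs.correct_negative(pat([[-1, 0], [3, 7]]))
        np.testing.assert_array_equal(p.intensity, [[0, 1], [4, 8]])

    def test_all_positive_unchanged(self):
        orig = pat([[1, 2], [3, 4]])
        assert fs.correct_negative(orig) is orig

    def test_constant_negative_becomes_zero(self):
        p = fs.correct_negative(pat(np.full((3, 3), -5.0)))
        np.testing.assert_array_equal(p.intensity, np.zeros((3, 3)))

    def test_preserves_pairwise_differences(self):
        rng = np.random.default_rng(1)
        data = rng.normal(-3, 10, (16, 16))
        p = fs.correct_negative(pat(data))
        np.testing.assert_allclose(np.diff(p.intensity), np.diff(data), atol=1e-12)

    def test_ignores_invalid_pixels(self):
        data = np.array([[5.0, -100.0], [7.0, 9.0]])
        mask = np.array([[True, False], [True, True]])
        assert fs.correct_negative(pat(data, mask)) .intensity[0, 0] == 5.0


class TestSubtractBackgroundImage:
    def test_none_background_is_identity(self):
        p = pat([[4.0]])
        assert fs.subtract_background_image(p, None) is p

    def test_self_subtraction_zeroes(self):
        p = pat([[4.0, 2.0]])
        out = fs.subtract_background_image(p, p)
        np.testing.assert_array_equal(out.intensity, [[0, 0]])

    def test_scale(self):
        out = fs.subtract_background_image(pat([[4.0]]), pat([[2.0]]), scale=0.5)
        assert out.intensity[0, 0] == 3.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fs.subtract_background_image(pat([[1.0]]), pat([[1.0, 2.0]]))

    def test_masks_anded(self):
        a = pat([[1.0, 2.0]], np.array([[True, False]]))
        b = pat([[1.0, 2.0]], np.array([[False, True]]))
        assert not fs.subtract_background_image(a, b).valid_mask.any()


class TestApplyMask:
    def test_lower_limit_marks_invalid(self):
        data = np.array([[5.0, 6.0], [6.2, 7.0]])
        out = fs.apply_mask(pat(data), fs.MaskSpec(lower_limit=6.1))
        np.testing.assert_array_equal(out.valid_mask, [[False, False], [True, True]])

    def test_infinite_limits_no_change(self):
        p = pat(np.arange(9.0).reshape(3, 3))
        out = fs.apply_mask(p, fs.MaskSpec())
        assert out is p

    def test_surviving_values_unchanged(self):
        data = np.arange(16.0).reshape(4, 4)
        out = fs.apply_mask(pat(data), fs.MaskSpec(lower_limit=5, upper_limit=11))
        np.testing.assert_array_equal(out.intensity, data)

    def test_everything_masked_then_integration_raises_empty(self):
        out = fs.apply_mask(pat(np.ones((8, 8))), fs.MaskSpec(lower_limit=2.0))
        assert not out.valid_mask.any()
        with pytest.raises(fs.errors.EmptyDataError):
            fs.integrate_radial(out, fs.Centre(4, 4))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            fs.MaskSpec(lower_limit=5, upper_limit=5)
        with pytest.raises(ValidationError):
            fs.MaskSpec(r_inner=10, r_outer=5)


class TestFillGaps:
    def symmetric_pattern(self, n=65):
        """Bitwise order-2 symmetric pattern about the integer centre."""
        centre = fs.Centre(n // 2, n // 2)  # odd n: point reflection = [::-1, ::-1]
        radius, azimuth = radial_coordinate((n, n), centre)
        data = 100.0 / (1.0 + radius) + np.cos(np.deg2rad(2 * azimuth)) * radius
        data = 0.5 * (data + data[::-1, ::-1])
        return fs.Pattern(data, np.ones((n, n), bool), "sym"), centre

    def test_symmetric_block_recovered_exactly(self):
        p, centre = self.symmetric_pattern()
        mask = p.valid_mask.copy()
        mask[10:20, 35:50] = False
        filled = fs.fill_gaps(p.replace(valid_mask=mask), centre)
        assert filled.valid_mask.all()
        np.testing.assert_array_equal(filled.intensity, p.intensity)

    def test_ring_interpolation_linear_in_azimuth(self):
        # ring values equal to azimuth in degrees; pixel + partner both masked
        n = 129
        centre = fs.Centre(64, 64)
        radius, azimuth = radial_coordinate((n, n), centre)
        ring = np.rint(radius).astype(int) == 40
        p = fs.Pattern(azimuth.copy(), np.ones((n, n), bool), "ring")
        gap = ring & (((azimuth > 10) & (azimuth < 20)) | ((azimuth > 190) & (azimuth < 200)))
        assert gap.any()
        filled = fs.fill_gaps(p.replace(valid_mask=~gap), centre)
        # interpolating a linear-in-azimuth signal is exact; the pixel nearest
        # 15 deg is filled with ~15
        np.testing.assert_allclose(filled.intensity[gap], azimuth[gap], atol=1e-9)
        sel = gap & (np.abs(azimuth - 15) < 1.0)
        assert np.allclose(filled.intensity[sel], 15, atol=1.0)

    def test_no_invalid_pixels_identity(self):
        p, centre = self.symmetric_pattern()
        assert fs.fill_gaps(p, centre) is p

    def test_idempotent(self):
        p, centre = self.symmetric_pattern()
        mask = p.valid_mask.copy()
        mask[5:25, 30:40] = False
        mask[50:55, 5:60] = False
        once = fs.fill_gaps(p.replace(valid_mask=mask), centre)
        twice = fs.fill_gaps(once, centre)
        np.testing.assert_array_equal(once.intensity, twice.intensity)
        np.testing.assert_array_equal(once.valid_mask, twice.valid_mask)

    def test_fully_invalid_ring_left_invalid_with_warning(self, caplog):
        n = 33
        centre = fs.Centre(16, 16)
        radius, _ = radial_coordinate((n, n), centre)
        mask = np.rint(radius).astype(int) != 5  # kill ring 5 completely
        p = fs.Pattern(np.ones((n, n)), mask, "x")
        with caplog.at_level("WARNING"):
            filled = fs.fill_gaps(p, centre)
        assert "no valid data" in caplog.text
        assert not filled.valid_mask.all()

    def test_random_masks_recover_symmetric_patterns(self):
        p, centre = self.symmetric_pattern()
        rng = np.random.default_rng(3)
        mask = rng.random(p.shape) > 0.2
        mask &= np.roll(np.roll(mask[::-1, ::-1], 1, 0), 1, 1) | True  # any mask
        filled = fs.fill_gaps(p.replace(valid_mask=mask), centre)
        # wherever the symmetric partner was valid, recovery is exact
        partner_valid = np.zeros_like(mask)
        rr, cc = np.nonzero(~mask)
        pr = np.rint(2 * centre.row - rr).astype(int)
        pc = np.rint(2 * centre.col - cc).astype(int)
        inb = (pr >= 0) & (pr < p.shape[0]) & (pc >= 0) & (pc < p.shape[1])
        exact = (rr[inb][mask[pr[inb], pc[inb]]], cc[inb][mask[pr[inb], pc[inb]]])
        np.testing.assert_array_equal(filled.intensity[exact], p.intensity[exact])
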