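"""Wavelength grid construction, black-white correction, cropping, ROI means."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopychl import (
    CalibrationPair,
    ConfigurationError,
    DegenerateCalibrationError,
    SpectrumSet,
    calibrate_reflectance,
    crop_interval,
    drop_boundary_bands,
    make_grid,
    roi_mean_spectrum,
)
from canopychl.io import read_envi_cube, write_envi_cube, read_mask, write_mask


def _set_from(values, grid, kind="dn"):
    return SpectrumSet(grid=grid, values=np.atleast_2d(values), kind=kind)


class TestMakeGrid:
    def test_sensor_grid_has_255_bands(self):
        grid = make_grid(400.0, 1000.0, 2.35)
        assert grid.n_bands == 255

    def test_single_band_interval(self):
        assert make_grid(400.0, 402.35, 2.35).n_bands == 1

    def test_first_center_is_half_step_offset(self):
        grid = make_grid(400.0, 1000.0, 2.35)
        assert grid.centers[0] == pytest.approx(401.175, abs=1e-9)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ConfigurationError):
            make_grid(400.0, 1000.0, 0.0)

    def test_centers_uniformly_spaced(self):
        grid = make_grid(400.0, 1000.0, 2.35)
        assert np.allclose(np.diff(grid.centers), 2.35)


class TestBoundaryRemoval:
    def test_255_to_253_effective_bands(self):
        grid = make_grid(400.0, 1000.0, 2.35)
        s = _set_from(np.zeros((2, 255)), grid, kind="reflectance")
        assert drop_boundary_bands(s, 1).n_bands == 253

    def test_middle_band_retained(self):
        grid = make_grid(0.0, 3.0, 1.0)
        s = _set_from(np.arange(3.0), grid, kind="reflectance")
        out = drop_boundary_bands(s, 1)
        assert out.n_bands == 1
        assert out.grid.centers[0] == pytest.approx(grid.centers[1])
        assert out.values[0, 0] == 1.0

    def test_zero_is_identity(self):
        grid = make_grid(0.0, 3.0, 1.0)
        s = _set_from(np.arange(3.0), grid, kind="reflectance")
        out = drop_boundary_bands(s, 0)
        assert np.array_equal(out.values, s.values)

    def test_too_few_bands_rejected(self):
        grid = make_grid(0.0, 2.0, 1.0)
        s = _set_from(np.zeros((1, 2)), grid)
        with pytest.raises(ConfigurationError):
            drop_boundary_bands(s, 1)


class TestBlackWhiteCorrection:
    grid = make_grid(0.0, 3.0, 1.0)
    cal = CalibrationPair(dn_dark=100.0, dn_white=900.0, rho_dark=0.05, rho_white=0.95)

    def test_panel_anchors(self):
        s = _set_from([[100.0, 900.0, 500.0]], self.grid)
        out = calibrate_reflectance(s, self.cal)
        # dark panel DN -> rho_dark, white -> rho_white, midpoint -> midpoint
        assert out.values[0] == pytest.approx([0.05, 0.95, 0.5])
        assert out.kind == "reflectance"

    def test_identity_panels(self):
        cal = CalibrationPair(dn_dark=0.0, dn_white=1.0, rho_dark=0.0, rho_white=1.0)
        s = _set_from([[0.0, 0.25, 1.0]], self.grid)
        assert calibrate_reflectance(s, cal).values[0] == pytest.approx([0.0, 0.25, 1.0])

    def test_degenerate_panels_rejected(self):
        with pytest.raises(DegenerateCalibrationError):
            CalibrationPair(dn_dark=5.0, dn_white=5.0)

    @given(
        dn=st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=3),
        shift=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_and_monotone(self, dn, shift):
        """Calibration is affine; raising any DN raises its reflectance."""
        s = _set_from([dn], self.grid)
        out = calibrate_reflectance(s, self.cal).values[0]
        s2 = _set_from([[dn[0] + shift, dn[1], dn[2]]], self.grid)
        out2 = calibrate_reflectance(s2, self.cal).values[0]
        assert out2[0] > out[0]
        assert out2[1] == out[1] and out2[2] == out[2]


class TestCropInterval:
    grid = make_grid(400.0, 1000.0, 2.35)

    def _set(self):
        return _set_from(np.zeros((1, 255)), self.grid, kind="reflectance")

    def test_full_range_identity(self):
        out = crop_interval(self._set(), 400.0, 1000.0)
        assert out.n_bands == 255

    def test_count_matches_enumeration(self):
        s = drop_boundary_bands(self._set(), 1)
        out = crop_interval(s, 400.0, 800.0)
        expected = sum(1 for c in s.grid.centers if 400.0 <= c <= 800.0)
        assert out.n_bands == expected
        assert out.grid.centers[-1] <= 800.0

    def test_empty_result_rejected(self):
        with pytest.raises(ConfigurationError):
            crop_interval(self._set(), 2000.0, 3000.0)

    def test_nested_crops_compose(self):
        s = self._set()
        once = crop_interval(s, 450.0, 700.0)
        twice = crop_interval(crop_interval(s, 420.0, 900.0), 450.0, 700.0)
        assert np.array_equal(once.grid.centers, twice.grid.centers)


class TestRoiMean:
    def test_single_pixel_mask(self):
        cube = np.arange(24.0).reshape(2, 3, 4)
        mask = np.zeros((2, 3), dtype=int)
        mask[1, 2] = 1
        assert np.array_equal(roi_mean_spectrum(cube, mask), cube[1, 2])

    def test_uniform_cube_any_mask(self):
        cube = np.full((3, 3, 5), 0.7)
        mask = np.eye(3, dtype=int)
        assert roi_mean_spectrum(cube, mask) == pytest.approx([0.7] * 5)

    def test_two_pixel_mean(self):
        cube = np.zeros((1, 2, 3))
        cube[0, 0] = [1.0, 2.0, 3.0]
        cube[0, 1] = [3.0, 4.0, 5.0]
        mask = np.ones((1, 2), dtype=int)
        assert roi_mean_spectrum(cube, mask) == pytest.approx([2.0, 3.0, 4.0])

    def test_empty_mask_rejected(self):
        with pytest.raises(ConfigurationError):
            roi_mean_spectrum(np.zeros((2, 2, 3)), np.zeros((2, 2), dtype=int))


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_cube_survives_round_trip(self, tmp_path, interleave):
        rng = np.random.default_rng(5)
        cube = rng.uniform(size=(4, 3, 6)).astype(np.float32)
        wl = np.linspace(400, 500, 6)
        hdr = tmp_path / f"scene_{interleave}.hdr"
        write_envi_cube(cube, hdr, interleave=interleave, wavelengths=wl)
        back, wl_back = read_envi_cube(hdr)
        assert back == pytest.approx(cube, abs=1e-6)
        assert wl_back == pytest.approx(wl, abs=1e-4)

    def test_mask_round_trip_and_roi(self, tmp_path):
        mask = np.array([[1, 0], [0, 1]])
        write_mask(mask, tmp_path / "mask.txt")
        back = read_mask(tmp_path / "mask.txt")
        assert np.array_equal(back, mask.astype(bool))
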